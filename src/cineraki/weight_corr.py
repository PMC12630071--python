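"""Weight-stability analysis: absolute-covariance Pearson correlation of
trained kernel weights across cardiac phases and slices.

The statistic is rho(X, Y) = |Cov(X, Y)| / (sigma_X * sigma_Y) between the
flattened weight vector of a reference frame (middle slice, middle phase by
convention) and every other frame's weights. Values near 1 mean the
interpolation weights — hence, implicitly, the coil sensitivities — are
stable across that dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grappa import GrappaWeights
from .nets import WeightSet

__all__ = ["WeightVector", "CorrelationTable", "flatten_weights", "pearson_abs", "correlation_table"]


class ZeroVarianceError(ValueError):
    """Correlation is undefined for a constant weight vector."""


@dataclass(frozen=True)
class WeightVector:
    """Flattened real view of one trained weight set, with provenance."""

    values: np.ndarray
    method: str = ""
    slice_index: int | None = None
    phase_index: int | None = None

    def __len__(self) -> int:
        return self.values.size


def flatten_weights(
    weights: WeightSet | GrappaWeights,
    slice_index: int | None = None,
    phase_index: int | None = None,
) -> WeightVector:
    """Flatten a trained weight set to a real vector with a fixed order.

    Network sets: layer by layer (main path then linear path), weights then
    bias. GRAPPA sets: per missing offset in increasing order, the complex
    matrix with real and imaginary parts interleaved. Biases are included.
    """
    if isinstance(weights, WeightSet):
        vals = weights.flatten()
        method = weights.method
    elif isinstance(weights, GrappaWeights):
        parts = []
        for d in sorted(weights.weights):
            w = weights.weights[d].ravel()
            v = np.empty(2 * w.size)
            v[0::2] = w.real
            v[1::2] = w.imag
            parts.append(v)
        vals = np.concatenate(parts)
        method = "grappa"
    else:
        raise TypeError(f"cannot flatten {type(weights).__name__}")
    return WeightVector(values=vals, method=method, slice_index=slice_index, phase_index=phase_index)


def _as_values(x) -> np.ndarray:
    v = x.values if isinstance(x, WeightVector) else np.asarray(x, dtype=float)
    return np.asarray(v, dtype=float).ravel()


def pearson_abs(X, Y) -> float:
    """|Cov(X, Y)| / (sigma_X sigma_Y), in [0, 1].

    Population moments; the denominator is computed as sqrt(var_X * var_Y)
    so that the self-correlation is exactly 1.0. Raises
    :class:`ZeroVarianceError` if either vector is constant.
    """
    x, y = _as_values(X), _as_values(Y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 entries")
    xm = x - x.mean()
    ym = y - y.mean()
    var_x = float(np.mean(xm**2))
    var_y = float(np.mean(ym**2))
    if var_x == 0.0 or var_y == 0.0:
        raise ZeroVarianceError("zero-variance weight vector")
    cov = float(np.mean(xm * ym))
    return abs(cov) / float(np.sqrt(var_x * var_y))


@dataclass
class CorrelationTable:
    """rho per (slice, phase) against a fixed reference frame."""

    rho: dict  # (slice, phase) -> float
    reference: tuple[int, int]

    def to_tsv(self) -> str:
        lines = [f"# reference slice={self.reference[0]} phase={self.reference[1]}", "slice\tphase\trho"]
        for (s, p), r in sorted(self.rho.items()):
            lines.append(f"{s}\t{p}\t{r:.6g}")
        return "\n".join(lines) + "\n"

    def by_slice(self, phase_average: bool = True) -> dict:
        """Mean rho per slice (averaged over phases)."""
        out: dict[int, list[float]] = {}
        for (s, _p), r in self.rho.items():
            out.setdefault(s, []).append(r)
        return {s: float(np.mean(v)) for s, v in sorted(out.items())}


def correlation_table(
    weight_vectors: list[WeightVector], reference: tuple[int, int]
) -> CorrelationTable:
    """Correlate every weight vector against the reference (slice, phase).

    All vectors must have equal length (same method and geometry); the
    reference must be present and correlates to exactly 1 with itself.
    """
    index = {(v.slice_index, v.phase_index): v for v in weight_vectors}
    if reference not in index:
        raise ValueError(f"reference frame {reference} not among the weight vectors")
    lengths = {len(v) for v in weight_vectors}
    if len(lengths) != 1:
        raise ValueError(f"weight vectors have differing lengths: {sorted(lengths)}")
    ref = index[reference]
    rho = {key: pearson_abs(ref, v) for key, v in index.items()}
    return CorrelationTable(rho=rho, reference=reference)


def plot_correlations(table: CorrelationTable, path: str) -> None:
    """Optional visualization: rho vs phase per slice, and mean rho vs slice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slices = sorted({s for s, _ in table.rho})
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for s in slices:
        phases = sorted(p for s2, p in table.rho if s2 == s)
        ax1.plot(phases, [table.rho[(s, p)] for p in phases], label=f"slice {s}")
    ax1.set_xlabel("cardiac phase")
    ax1.set_ylabel(r"$\rho$")
    ax1.legend(fontsize=6)
    by_slice = table.by_slice()
    ax2.plot(list(by_slice), list(by_slice.values()), "o-")
    ax2.set_xlabel("slice")
    ax2.set_ylabel(r"mean $\rho$ over phases")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
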