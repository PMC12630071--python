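"""Training/reuse orchestration for multi-slice, multi-phase cine stacks.

A strategy decides which (slice, phase) frames get their own trained weight
set and which frames reuse weights trained elsewhere:

* ``per_frame`` — every frame trains its own weights (the reference
  scan-specific pipeline; most expensive).
* ``mp``       — multi-phase sharing: one phase per slice is trained and its
  weights reconstruct all phases of that slice (coil sensitivities are
  phase-stable).
* ``ms``       — multi-slice sharing in groups of ``group_size`` consecutive
  slices: the group's middle slice is trained at every phase; with
  ``all_slices_one_model`` a single model per phase is trained jointly on
  every slice's ACS.
* ``mp_ms``    — the combined scheme: per group of ``group_size`` (3 by
  default) slices, train the middle slice at a single phase and reuse those
  weights for the whole group at every phase (fastest).

Timing is instrumented per stage (data loading, training, evaluation,
image reconstruction) with wall-clock deltas.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import grappa as _grappa
from . import nets as _nets
from .sampling import SamplingMask, extract_acs, undersample
from .transforms import data_consistency, ifft2c, sos_combine

__all__ = ["StrategySpec", "TrainingPlan", "PlanEntry", "ReconResult", "make_plan", "run_strategy", "ms_variants"]

STRATEGY_NAMES = ("per_frame", "mp", "ms", "mp_ms")
GROUP_SIZES = (1, 3, 5, 9)


@dataclass(frozen=True)
class StrategySpec:
    name: str
    group_size: int = 3
    all_slices_one_model: bool = False
    phase_selection: str = "fixed"  # "fixed" (middle phase) or "random"
    fixed_phase: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; expected one of {STRATEGY_NAMES}")
        if not self.all_slices_one_model and self.group_size not in GROUP_SIZES:
            raise ValueError(f"group_size must be one of {GROUP_SIZES}")
        if self.phase_selection not in ("fixed", "random"):
            raise ValueError("phase_selection must be 'fixed' or 'random'")


@dataclass(frozen=True)
class PlanEntry:
    """One training event: ACS source frames and the frames its weights cover."""

    train_frames: tuple  # ((slice, phase), ...) — ACS data used jointly
    cover: tuple  # ((slice, phase), ...) — frames reconstructed with these weights


@dataclass(frozen=True)
class TrainingPlan:
    entries: tuple
    n_slices: int
    n_phases: int

    @property
    def n_trainings(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        """Every frame of the stack must be covered exactly once."""
        seen = [f for e in self.entries for f in e.cover]
        expected = {(s, p) for s in range(self.n_slices) for p in range(self.n_phases)}
        if len(seen) != len(set(seen)) or set(seen) != expected:
            raise ValueError("plan does not cover every frame exactly once")

    def to_table(self) -> str:
        lines = ["trained_frames\tcovered_frames"]
        for e in self.entries:
            t = ",".join(f"{s}:{p}" for s, p in e.train_frames)
            c = ",".join(f"{s}:{p}" for s, p in e.cover)
            lines.append(f"{t}\t{c}")
        return "\n".join(lines) + "\n"


def _slice_groups(n_slices: int, size: int) -> list[list[int]]:
    return [list(range(i, min(i + size, n_slices))) for i in range(0, n_slices, size)]


def _train_slice(group: list[int]) -> int:
    return group[(len(group) - 1) // 2]


def _pick_phase(spec: StrategySpec, n_phases: int, key: int) -> int:
    if spec.phase_selection == "random":
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(key,)))
        return int(rng.integers(n_phases))
    if spec.fixed_phase is not None:
        if not (0 <= spec.fixed_phase < n_phases):
            raise ValueError(f"fixed_phase {spec.fixed_phase} outside [0, {n_phases})")
        return spec.fixed_phase
    return n_phases // 2


def make_plan(n_slices: int, n_phases: int, spec: StrategySpec) -> TrainingPlan:
    """Build the training plan for a stack of ``n_slices`` x ``n_phases``.

    Training counts: ``per_frame`` -> S*P, ``mp`` -> S, ``ms(1/B)`` ->
    ceil(S/B)*P (one per group per phase), ``mp_ms`` -> ceil(S/B).
    """
    if n_slices < 1 or n_phases < 1:
        raise ValueError("n_slices and n_phases must be >= 1")
    if spec.name in ("ms", "mp_ms") and not spec.all_slices_one_model:
        if spec.group_size > n_slices:
            raise ValueError(f"group_size {spec.group_size} > n_slices {n_slices}")

    entries = []
    if spec.name == "per_frame":
        for s in range(n_slices):
            for p in range(n_phases):
                entries.append(PlanEntry(((s, p),), ((s, p),)))
    elif spec.name == "mp":
        for s in range(n_slices):
            tp = _pick_phase(spec, n_phases, s)
            entries.append(PlanEntry(((s, tp),), tuple((s, p) for p in range(n_phases))))
    elif spec.name == "ms":
        if spec.all_slices_one_model:
            for p in range(n_phases):
                all_s = tuple((s, p) for s in range(n_slices))
                entries.append(PlanEntry(all_s, all_s))
        else:
            for group in _slice_groups(n_slices, spec.group_size):
                ts = _train_slice(group)
                for p in range(n_phases):
                    entries.append(
                        PlanEntry(((ts, p),), tuple((s, p) for s in group))
                    )
    elif spec.name == "mp_ms":
        for gi, group in enumerate(_slice_groups(n_slices, spec.group_size)):
            ts = _train_slice(group)
            tp = _pick_phase(spec, n_phases, gi)
            entries.append(
                PlanEntry(
                    ((ts, tp),),
                    tuple((s, p) for s in group for p in range(n_phases)),
                )
            )
    plan = TrainingPlan(entries=tuple(entries), n_slices=n_slices, n_phases=n_phases)
    plan.validate()
    return plan


def ms_variants(n_slices: int = 9) -> dict[str, StrategySpec]:
    """The canonical multi-slice ablation for a 9-slice stack.

    ``1/1`` trains every slice itself, ``9/9`` trains one joint model per
    phase on all slices, ``1/9``, ``1/5`` and ``1/3`` train the middle slice
    of groups of 9, 5 and 3 (the trailing group may be shorter).
    """
    return {
        "1/1": StrategySpec("ms", group_size=1),
        "9/9": StrategySpec("ms", all_slices_one_model=True),
        "1/9": StrategySpec("ms", group_size=min(9, n_slices)),
        "1/5": StrategySpec("ms", group_size=5),
        "1/3": StrategySpec("ms", group_size=3),
    }


@dataclass
class ReconResult:
    """Reconstructed SoS images with the four-part timing breakdown.

    ``load_s`` and ``train_s`` are attributed to the frames that were
    trained (split evenly when a weight set trains on several frames);
    ``eval_s`` and ``recon_s`` are recorded per reconstructed frame.
    """

    images: np.ndarray  # real [S, P, ny, nx]
    load_s: np.ndarray  # [S, P]
    train_s: np.ndarray
    eval_s: np.ndarray
    recon_s: np.ndarray
    plan: TrainingPlan
    weights: list = field(default_factory=list)

    @property
    def timing(self) -> dict:
        return {
            "load_s": float(self.load_s.sum()),
            "train_s": float(self.train_s.sum()),
            "eval_s": float(self.eval_s.sum()),
            "recon_s": float(self.recon_s.sum()),
        }

    @property
    def total_time(self) -> float:
        return float(sum(self.timing.values()))


def run_strategy(
    cine: np.ndarray,
    mask: SamplingMask,
    method: str,
    spec: StrategySpec,
    hyper: "_nets.TrainingHyper | None" = None,
    grappa_spec: "_grappa.GrappaKernelSpec | None" = None,
    ridge: float = _grappa.DEFAULT_RIDGE,
) -> ReconResult:
    """Reconstruct a full cine stack under a training-reuse strategy.

    ``cine`` is the fully sampled complex stack ``[S, P, C, ky, kx]``
    (retrospectively undersampled here with ``mask``); ``method`` is one of
    ``grappa``, ``sraki``, ``raki``, ``rraki``. Per-slice weight sets keep
    their (slice, phase) training provenance.
    """
    cine = np.asarray(cine)
    if cine.ndim != 5:
        raise ValueError("cine must be [slice, phase, coil, ky, kx]")
    S, P, C, ny, nx = cine.shape
    method = method.lower()
    if method not in ("grappa",) + _nets.METHODS:
        raise ValueError(f"unknown method {method!r}")
    plan = make_plan(S, P, spec)
    hyper = hyper or _nets.TrainingHyper()

    images = np.empty((S, P, ny, nx))
    load_s = np.zeros((S, P))
    train_s = np.zeros((S, P))
    eval_s = np.zeros((S, P))
    recon_s = np.zeros((S, P))
    all_weights = []

    net_spec = None if method == "grappa" else _nets.build_network(method, C)
    g_spec = grappa_spec or _grappa.GrappaKernelSpec(R=mask.R)

    for entry in plan.entries:
        # --- load: undersample and extract the ACS of the training frames
        t0 = time.perf_counter()
        acs_blocks = [
            extract_acs(undersample(cine[s, p], mask), mask) for s, p in entry.train_frames
        ]
        dt = (time.perf_counter() - t0) / len(entry.train_frames)
        for s, p in entry.train_frames:
            load_s[s, p] += dt

        # --- train / calibrate
        t0 = time.perf_counter()
        if method == "grappa":
            ws = _grappa.grappa_calibrate(
                acs_blocks if len(acs_blocks) > 1 else acs_blocks[0], g_spec, ridge=ridge
            )
            ws = _grappa.GrappaWeights(
                spec=ws.spec,
                n_coils=ws.n_coils,
                weights=ws.weights,
                provenance={"frames": entry.train_frames, "method": "grappa"},
            )
        else:
            pairs = [
                _nets.make_training_pair(block, mask, net_spec) for block in acs_blocks
            ]
            ws = _nets.train_network(
                net_spec,
                pairs if len(pairs) > 1 else pairs[0],
                hyper,
                provenance={"frames": entry.train_frames, "method": method},
            )
        dt = (time.perf_counter() - t0) / len(entry.train_frames)
        for s, p in entry.train_frames:
            train_s[s, p] += dt
        all_weights.append(ws)

        # --- apply + reconstruct every covered frame
        for s, p in entry.cover:
            t0 = time.perf_counter()
            measured = undersample(cine[s, p], mask)
            if method == "grappa":
                filled = _grappa.grappa_apply(ws, measured, mask)
                filled = data_consistency(filled, measured, mask)
            else:
                filled = _nets.apply_network(ws, measured, mask)
            t1 = time.perf_counter()
            images[s, p] = sos_combine(ifft2c(filled))
            t2 = time.perf_counter()
            eval_s[s, p] += t1 - t0
            recon_s[s, p] += t2 - t1

    return ReconResult(
        images=images,
        load_s=load_s,
        train_s=train_s,
        eval_s=eval_s,
        recon_s=recon_s,
        plan=plan,
        weights=all_weights,
    )
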