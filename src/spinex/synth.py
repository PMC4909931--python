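"""Synthetic-data generation with known ground truth.

Everything the analysis pipeline consumes can be generated here: the
spin-lock condition designs used in the study (on-resonance power series
100-2000 Hz; off-resonance series at 100-300 Hz with offsets up to
3.5x the lock power; delay grids to 60 ms for the three-way-junction
construct and 150 ms for the isolated hairpin), intensity-decay tables
under two-state exchange with the published global-fit parameters as
ground truth, and replicate SHAPE profiles with paired/unpaired reactivity
statistics.  All generators are deterministic under a fixed seed.

The per-residue R1 = 2 s^-1 and R2 = 16 s^-1 are nominal values typical
of imino 15N at 10 degC; they are free fit parameters downstream, so
their exact values do not bias exchange-parameter recovery.  The default
relative intensity noise is 2%.

SHAPE noise model: each replicate lane carries a global log-normal scale
factor (log-sd 0.19, emulating loading/injection differences between
capillary runs) on top of per-position log-normal measurement noise
(log-sd 0.06); the combined per-measurement spread is ~20%.  The lane
scale is exactly what normalization against the 3' single-stranded
reference removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import r1rho_numeric, simulate_magnetization, aligned_initial_state
from .laguerre import r1rho_laguerre
from .core import ExchangeParams, FieldContext, SpinExchangeModel, SpinLockCondition
from .decay import DecayCurve
from .shape import ARTIFACT_FLAG, CONTROL_FLAG, REFERENCE_FLAG, ShapeProfile

__all__ = [
    "TruthRecord",
    "SCENARIOS",
    "standard_design",
    "scenario_truth",
    "generate_rd_dataset",
    "generate_shape_dataset",
    "default_structure_states",
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one synthetic dataset: shared exchange, per-residue
    spin models, relative intensity noise, seed and design label."""

    exchange: ExchangeParams
    models: tuple[SpinExchangeModel, ...]
    noise_sigma: float
    seed: int
    design_label: str


_DELAY_MAX_S = {"tP5abc": 0.060, "iP5c": 0.150}

# published global-fit truths: (pB, kex s^-1, {residue: dw_ppm})
_SCENARIO_TABLE = {
    "tP5abc_noMg": (
        0.029,
        423.0,
        {"G164": 1.8, "U167": 3.9, "G174": 4.3, "G175": 1.4, "G176": -2.0},
    ),
    "tP5abc_Mg": (0.010, 329.0, {"G174": 3.9, "U167": 4.1}),
    "iP5c_noMg": (
        0.034,
        323.0,
        {"G164": 1.8, "U167": 3.9, "G174": 4.3, "G175": 1.4, "G176": -2.0},
    ),
    "iP5c_Mg": (0.005, 964.0, {"G174": 3.3, "U167": 2.5}),
}
SCENARIOS = tuple(_SCENARIO_TABLE)

_NOMINAL_R1 = 2.0
_NOMINAL_R2 = 16.0

# nominal major-state imino 15N shifts (ppm), used only as labels/anchors
_GS_SHIFT_PPM = {"G164": 145.0, "U167": 157.8, "G174": 143.2, "G175": 147.0, "G176": 147.5}


def standard_design(
    variant: str,
    n_onres_powers: int = 12,
    n_offres_powers: int = 3,
    n_offsets: int = 10,
    n_delays: int = 6,
) -> list[SpinLockCondition]:
    """Spin-lock condition grid for one construct variant.

    On-resonance: ``n_onres_powers`` log-spaced powers 100-2000 Hz at zero
    offset.  Off-resonance: ``n_offres_powers`` log-spaced powers
    100-300 Hz, each with ``n_offsets`` offsets at +/-(0.7..3.5)x power.
    Delays: ``n_delays`` evenly spaced values from 0 to the variant's
    maximum (60 ms for tP5abc, 150 ms for iP5c).
    """
    if variant not in _DELAY_MAX_S:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_DELAY_MAX_S)}")
    delays = tuple(np.linspace(0.0, _DELAY_MAX_S[variant], n_delays))
    conditions = [
        SpinLockCondition(spinlock_power_hz=float(p), carrier_offset_hz=0.0, duration_grid_s=delays)
        for p in np.geomspace(100.0, 2000.0, n_onres_powers)
    ]
    if n_offsets % 2:
        raise ValueError("n_offsets must be even (symmetric +/- offsets)")
    fractions = np.linspace(0.7, 3.5, n_offsets // 2)
    for p in np.geomspace(100.0, 300.0, n_offres_powers):
        for frac in fractions:
            for sign in (1.0, -1.0):
                conditions.append(
                    SpinLockCondition(
                        spinlock_power_hz=float(p),
                        carrier_offset_hz=float(sign * frac * p),
                        duration_grid_s=delays,
                    )
                )
    return conditions


def scenario_truth(scenario: str, noise_sigma: float = 0.02, seed: int = 0) -> TruthRecord:
    """Ground-truth record for one study scenario (construct x Mg2+ state),
    using the published globally fitted exchange parameters and per-residue
    15N shift differences."""
    if scenario not in _SCENARIO_TABLE:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIO_TABLE)}")
    pb, kex, dws = _SCENARIO_TABLE[scenario]
    exchange = ExchangeParams(p_minor=pb, k_ex=kex)
    models = tuple(
        SpinExchangeModel(
            residue_label=res,
            r1=_NOMINAL_R1,
            r2=_NOMINAL_R2,
            ground_state_shift_ppm=_GS_SHIFT_PPM[res],
            delta_omega_ppm=dw,
            exchange=exchange,
        )
        for res, dw in sorted(dws.items())
    )
    return TruthRecord(
        exchange=exchange,
        models=models,
        noise_sigma=noise_sigma,
        seed=seed,
        design_label=scenario.split("_")[0],
    )


def generate_rd_dataset(
    truth: TruthRecord,
    design,
    fieldctx: FieldContext,
    mode: str = "fast",
    seed: int | None = None,
    i0: float = 100.0,
) -> list[DecayCurve]:
    """Intensity-decay tables for every (residue, condition) pair.

    mode="fast": analytic monoexponential I(t) = I0 exp(-R t) with R from
    the closed-form two-state rate — truth lives in the model class the
    pipeline fits, so recovery tests probe the fitting machinery alone.
    mode="numeric": monoexponential at the Bloch-McConnell eigenvalue rate.
    mode="full": projection of the full simulated Bloch-McConnell trace
    onto the lock direction.  The numeric/full modes carry the
    approximation's small model error into the data and are what the
    oracle suite exercises.  Multiplicative Gaussian noise of fraction
    ``truth.noise_sigma`` is applied; ``seed`` defaults to ``truth.seed``.
    """
    if mode not in ("fast", "numeric", "full"):
        raise ValueError(f"mode must be 'fast', 'numeric' or 'full', got {mode!r}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    curves = []
    for model in truth.models:
        for cond in design:
            t = np.asarray(cond.duration_grid_s)
            if mode == "fast":
                rate = r1rho_laguerre(model, cond, fieldctx)
                ideal = i0 * np.exp(-rate * t)
            elif mode == "numeric":
                rate = r1rho_numeric(model, cond, fieldctx)
                ideal = i0 * np.exp(-rate * t)
            else:
                trace = simulate_magnetization(model, cond, fieldctx)
                m0 = aligned_initial_state(model, cond, fieldctx)
                w = m0 / np.linalg.norm(m0)
                signal = trace.vectors @ w
                ideal = i0 * signal / signal[0]
            sigma = truth.noise_sigma * np.abs(ideal)
            noisy = ideal + rng.normal(0.0, 1.0, size=t.shape) * sigma
            curves.append(
                DecayCurve(
                    residue_label=model.residue_label,
                    condition=cond,
                    delays_s=t,
                    intensities=noisy,
                    # the generator knows its own noise; downstream error
                    # estimation uses these per-point sigmas when present
                    intensity_sigma=sigma if truth.noise_sigma > 0 else None,
                )
            )
    return curves


# ---------------------------------------------------------------------------
# SHAPE generator

_PAIRED_MEDIAN = 0.2
_UNPAIRED_MEDIAN = 1.0
_CONTROL_SCALE = 0.96
_LANE_SCALE_SIGMA = 0.19
_POSITION_NOISE_SIGMA = 0.06

_STEM5 = 4  # 5' hairpin stem, paired
_LOOP5 = 6  # 5' hairpin loop, unpaired internal control
_BUFFER = 5  # single-stranded buffer
_REF3 = 10  # 3' single-stranded normalization reference


def default_structure_states() -> dict[str, str]:
    """Two core secondary structures emulating a register-shifted helix:
    four positions flip paired->unpaired and four flip the other way
    between the conditions."""
    return {
        "condition_a": "pppppuuuupppppuu",
        "condition_b": "puuuupppppppppuu",
    }


def generate_shape_dataset(
    structure_states: dict[str, str],
    replicates: int = 2,
    seed: int = 0,
    artifact_positions=(),
    lane_scale_sigma: float = _LANE_SCALE_SIGMA,
    position_noise_sigma: float = _POSITION_NOISE_SIGMA,
) -> dict[str, list[ShapeProfile]]:
    """Raw replicate SHAPE profiles for each condition.

    ``structure_states`` maps condition label -> 'p'/'u' string over the
    core region; the generator adds a 5' control hairpin, single-stranded
    buffers and the 3' reference tail around it.  Reactivities are
    log-normal (paired median 0.2, unpaired median 1.0), the control loop
    is scaled by 0.96, and each replicate lane carries a global log-normal
    scale on top of per-position noise.  Deterministic under ``seed``.
    """
    if replicates < 2:
        raise ValueError(f"need >= 2 replicates, got {replicates}")
    core_lens = {len(s) for s in structure_states.values()}
    if len(core_lens) != 1:
        raise ValueError("all conditions must share the core length")
    core_len = core_lens.pop()

    n_total = 2 * _STEM5 + _LOOP5 + _BUFFER + core_len + _REF3
    positions = np.arange(1, n_total + 1)
    core_start = 2 * _STEM5 + _LOOP5 + _BUFFER  # 0-based index of first core position

    annotations: list[set[str]] = [set() for _ in range(n_total)]
    for i in range(_STEM5, _STEM5 + _LOOP5):
        annotations[i].add(CONTROL_FLAG)
    for i in range(n_total - _REF3, n_total):
        annotations[i].add(REFERENCE_FLAG)
    for pos in artifact_positions:
        annotations[int(pos) - 1].add(ARTIFACT_FLAG)

    rng = np.random.default_rng(seed)
    out: dict[str, list[ShapeProfile]] = {}
    for label in sorted(structure_states):
        states = structure_states[label]
        if set(states) - {"p", "u"}:
            raise ValueError(f"{label}: structure string must contain only 'p'/'u'")
        truth = np.empty(n_total)
        truth[:_STEM5] = _PAIRED_MEDIAN
        truth[_STEM5 : _STEM5 + _LOOP5] = _UNPAIRED_MEDIAN * _CONTROL_SCALE
        truth[_STEM5 + _LOOP5 : 2 * _STEM5 + _LOOP5] = _PAIRED_MEDIAN
        truth[2 * _STEM5 + _LOOP5 : core_start] = _UNPAIRED_MEDIAN
        for j, s in enumerate(states):
            truth[core_start + j] = _PAIRED_MEDIAN if s == "p" else _UNPAIRED_MEDIAN
        truth[n_total - _REF3 :] = _UNPAIRED_MEDIAN

        reps = []
        for _ in range(replicates):
            lane = np.exp(rng.normal(0.0, lane_scale_sigma))
            noise = np.exp(rng.normal(0.0, position_noise_sigma, size=n_total))
            reps.append(
                ShapeProfile(
                    positions=positions,
                    reactivities=truth * lane * noise,
                    sem=None,
                    annotations=[frozenset(a) for a in annotations],
                    condition_label=label,
                )
            )
        out[label] = reps
    return out
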