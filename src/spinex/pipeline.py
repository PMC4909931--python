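"""End-to-end glue: decay curves -> R1rho profiles -> shared-parameter fit.

These helpers wire the per-stage modules together the way the CLI and the
parameter-recovery harness use them.  All randomness flows from a single
integer seed through a SeedSequence, so every stage is reproducible.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .core import FieldContext
from .decay import fit_decay
from .globalfit import GlobalFitResult, RDProfile, fit_two_state_global, mc_fit_errors
from .synth import TruthRecord, generate_rd_dataset, scenario_truth, standard_design

__all__ = ["curves_to_profiles", "analyze_dispersion", "simulate_and_fit"]


def curves_to_profiles(
    curves, n_mc: int = 50, seed: int = 0
) -> list[RDProfile]:
    """Fit every decay curve and group the R1rho points by residue.

    Each curve's Monte-Carlo error loop gets its own child seed derived
    from ``seed``.
    """
    curves = list(curves)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(curves)) % (2**31)
    by_residue = defaultdict(list)
    for curve, s in zip(curves, child_seeds):
        by_residue[curve.residue_label].append(fit_decay(curve, n_mc=n_mc, seed=int(s)))
    return [RDProfile(residue_label=res, points=tuple(pts)) for res, pts in sorted(by_residue.items())]


def analyze_dispersion(
    curves,
    fieldctx: FieldContext,
    n_mc_decay: int = 50,
    n_mc_fit: int = 50,
    seed: int = 0,
) -> GlobalFitResult:
    """Full analysis of a decay-curve collection: monoexponential R1rho
    extraction with Monte-Carlo errors, then a global two-state fit with
    shared exchange parameters and Monte-Carlo parameter uncertainties."""
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    profiles = curves_to_profiles(curves, n_mc=n_mc_decay, seed=int(ss[0]))
    result = fit_two_state_global(profiles, fieldctx)
    return mc_fit_errors(result, profiles, fieldctx, n_iter=n_mc_fit, seed=int(ss[1]))


def simulate_and_fit(
    scenario: str,
    seed: int,
    fieldctx: FieldContext | None = None,
    noise_sigma: float = 0.02,
    mode: str = "fast",
    n_mc_decay: int = 50,
    n_mc_fit: int = 50,
) -> tuple[TruthRecord, GlobalFitResult]:
    """Parameter-recovery harness: simulate a scenario's dataset at the
    standard condition design and analyse it end-to-end."""
    if fieldctx is None:
        fieldctx = FieldContext()
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    truth = scenario_truth(scenario, noise_sigma=noise_sigma, seed=int(ss[0]))
    design = standard_design(truth.design_label)
    curves = generate_rd_dataset(truth, design, fieldctx, mode=mode)
    result = analyze_dispersion(
        curves, fieldctx, n_mc_decay=n_mc_decay, n_mc_fit=n_mc_fit, seed=int(ss[1])
    )
    return truth, result
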