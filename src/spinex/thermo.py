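"""Thermodynamic interpretation of fitted populations and rates.

A state populated at fraction p relative to the remainder of the ensemble
has a folding free energy dG = -RT ln(p/(1-p)) (kcal/mol) and an
equilibrium constant K = p/(1-p).  Exchange parameters decompose into
microscopic rates k1 = pB*kex and k-1 = (1-pB)*kex.

Two conventions are exposed for the equilibrium constant between two
minor states measured against the same ground state: the small-population
"ratio" approximation K ~ p_a/p_b and the exact odds ratio
(p_a/(1-p_a))/(p_b/(1-p_b)).  Likewise free-energy ladders can be built
from raw populations or from already-rounded dG values; the two paths
differ at the second decimal and are never silently reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import DEFAULT_TEMPERATURE_K, ExchangeParams

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoState",
    "population_to_dG",
    "dG_to_population",
    "exchange_to_rates",
    "predict_K_ES_Nat",
    "K_fold_from_population",
    "energy_ladder",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3


def population_to_dG(p: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Free energy (kcal/mol) of a state populated at fraction p:
    -RT ln(p/(1-p)).  Positive for p < 0.5 (state above the reference)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"population must be in (0, 1), got {p}")
    return -GAS_CONSTANT_KCAL * temperature_k * math.log(p / (1.0 - p))


def dG_to_population(dg_kcal: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse of :func:`population_to_dG`."""
    x = math.exp(-dg_kcal / (GAS_CONSTANT_KCAL * temperature_k))
    return x / (1.0 + x)


@dataclass(frozen=True)
class ThermoState:
    """A conformational state with population, free energy and temperature,
    all relative to the same reference ensemble.  Construct from either the
    population (:meth:`from_population`) or the free energy
    (:meth:`from_delta_g`); the two fields are kept exactly consistent."""

    label: str
    population: float
    delta_g_kcal: float
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not 0.0 < self.population < 1.0:
            raise ValueError(f"{self.label}: population must be in (0, 1)")
        expected = population_to_dG(self.population, self.temperature_k)
        if abs(expected - self.delta_g_kcal) > 1e-9:
            raise ValueError(
                f"{self.label}: delta_g ({self.delta_g_kcal}) inconsistent with "
                f"population ({self.population}); expected {expected}"
            )

    @classmethod
    def from_population(
        cls, label: str, p: float, temperature_k: float = DEFAULT_TEMPERATURE_K
    ) -> "ThermoState":
        return cls(label, p, population_to_dG(p, temperature_k), temperature_k)

    @classmethod
    def from_delta_g(
        cls, label: str, dg_kcal: float, temperature_k: float = DEFAULT_TEMPERATURE_K
    ) -> "ThermoState":
        return cls(label, dG_to_population(dg_kcal, temperature_k), dg_kcal, temperature_k)


def exchange_to_rates(exchange: ExchangeParams) -> tuple[float, float]:
    """Microscopic rates (k1, k-1) in s^-1 from (pB, kex)."""
    return exchange.k_forward, exchange.k_reverse


def predict_K_ES_Nat(p_nat: float, p_es: float, mode: str = "ratio") -> float:
    """Equilibrium constant for the minor-state -> native transition.

    mode="ratio" (default): the small-population approximation p_nat/p_es.
    mode="exact": the odds ratio (p_nat/(1-p_nat)) / (p_es/(1-p_es)).
    Both populations must be measured against the same ground state.
    """
    for name, p in (("p_nat", p_nat), ("p_es", p_es)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {p}")
    if mode == "ratio":
        return p_nat / p_es
    if mode == "exact":
        return (p_nat / (1.0 - p_nat)) / (p_es / (1.0 - p_es))
    raise ValueError(f"unknown mode {mode!r}")


def K_fold_from_population(p_fold: float) -> float:
    """Folding equilibrium constant K = p/(1-p)."""
    if not 0.0 < p_fold < 1.0:
        raise ValueError(f"population must be in (0, 1), got {p_fold}")
    return p_fold / (1.0 - p_fold)


def energy_ladder(states) -> "pd.DataFrame":
    """Table of pairwise free-energy differences ddG(a, b) = dG_a - dG_b.

    All states must share a temperature (they are defined against the same
    reference ensemble).  Returns a DataFrame with columns
    (state_a, state_b, ddg_kcal) over all ordered pairs a != b; the table
    is antisymmetric (ddG(a,b) = -ddG(b,a)) and empty for fewer than two
    states.
    """
    states = list(states)
    temps = {s.temperature_k for s in states}
    if len(temps) > 1:
        raise ValueError(f"states at mixed temperatures: {sorted(temps)}")
    rows = [
        (a.label, b.label, a.delta_g_kcal - b.delta_g_kcal)
        for a in states
        for b in states
        if a.label != b.label
    ]
    return pd.DataFrame(rows, columns=["state_a", "state_b", "ddg_kcal"])
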