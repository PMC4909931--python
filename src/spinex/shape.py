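"""SHAPE reactivity processing: replicate aggregation, normalization,
internal-control diagnostics and differential-reactivity maps.

The pipeline starts from per-position raw reactivities (capillary-trace
alignment and band quantification are upstream).  Replicates are averaged
with the standard error of the mean as the per-position error; profiles
are normalized by the mean raw reactivity over an annotated set of
single-stranded 3'-end reference nucleotides; a 5'-hairpin loop serves as
an internal control whose normalized mean should sit near 1.  Differential
maps between two conditions subtract normalized profiles position-wise
with errors added in quadrature.

Annotations are per-position flag sets; recognised flags:

- ``reference_3prime``:   normalization reference nucleotide
- ``control_5prime_loop``: internal-control loop nucleotide
- ``rt_stop_artifact``:   position confounded by reverse-transcriptase
  stops — carried through differentials with a caveat flag, never dropped
  silently (such positions are identified manually, not auto-detected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_FLAG",
    "CONTROL_FLAG",
    "ARTIFACT_FLAG",
    "ShapeProfile",
    "ControlCheck",
    "DifferentialProfile",
    "aggregate_replicates",
    "normalize",
    "control_check",
    "differential",
]

REFERENCE_FLAG = "reference_3prime"
CONTROL_FLAG = "control_5prime_loop"
ARTIFACT_FLAG = "rt_stop_artifact"


@dataclass(frozen=True)
class ShapeProfile:
    """Per-nucleotide SHAPE reactivities for one condition.

    ``sem`` may be None for a single raw replicate (before aggregation);
    ``annotations`` holds one flag set per position.
    """

    positions: np.ndarray
    reactivities: np.ndarray
    sem: np.ndarray | None
    annotations: tuple[frozenset[str], ...]
    condition_label: str = ""
    normalized: bool = False
    n_floored: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        rea = np.asarray(self.reactivities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "reactivities", rea)
        if len(pos) != len(rea) or len(pos) != len(self.annotations):
            raise ValueError("positions, reactivities and annotations must align")
        if len(np.unique(pos)) != len(pos):
            raise ValueError("duplicate positions")
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if sem.shape != rea.shape or np.any(sem < 0):
                raise ValueError("sem must match reactivities and be >= 0")
            object.__setattr__(self, "sem", sem)
        object.__setattr__(self, "annotations", tuple(frozenset(a) for a in self.annotations))

    def mask(self, flag: str) -> np.ndarray:
        return np.array([flag in a for a in self.annotations])

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "reactivity": self.reactivities,
                "sem": self.sem if self.sem is not None else np.nan,
                "flags": [",".join(sorted(a)) for a in self.annotations],
                "condition": self.condition_label,
                "replicate": replicate,
            }
        )


def _check_matched(a: ShapeProfile, b: ShapeProfile) -> None:
    if a.positions.shape != b.positions.shape or np.any(a.positions != b.positions):
        raise ValueError("profiles cover different position sets")


def aggregate_replicates(replicates) -> ShapeProfile:
    """Mean reactivity and standard error of the mean over >= 2 replicates.

    Replicates must cover identical positions; annotations are taken from
    the first replicate (they describe the construct, not the measurement).
    """
    replicates = list(replicates)
    if len(replicates) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(replicates)}")
    first = replicates[0]
    for rep in replicates[1:]:
        _check_matched(first, rep)
    stack = np.vstack([r.reactivities for r in replicates])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(replicates))
    return ShapeProfile(
        positions=first.positions,
        reactivities=mean,
        sem=sem,
        annotations=first.annotations,
        condition_label=first.condition_label,
        normalized=first.normalized,
    )


def normalize(profile: ShapeProfile, reference_positions=None) -> ShapeProfile:
    """Divide reactivities (and sem) by the mean raw reactivity over the
    reference set.

    The reference set is the annotated ``reference_3prime`` positions
    unless given explicitly — the identity of the single-stranded
    reference nucleotides is construct-specific and therefore an input,
    never hard-coded.  Negative raw reactivities are floored at zero first
    and the count recorded on the result.
    """
    if reference_positions is None:
        ref_mask = profile.mask(REFERENCE_FLAG)
    else:
        ref_mask = np.isin(profile.positions, np.asarray(list(reference_positions), dtype=int))
    if not np.any(ref_mask):
        raise ValueError("empty normalization reference set")
    rea = profile.reactivities.copy()
    n_floored = int(np.sum(rea < 0))
    if n_floored:
        warnings.warn(f"floored {n_floored} negative reactivities at 0", stacklevel=2)
        rea = np.maximum(rea, 0.0)
    ref_mean = float(rea[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    return ShapeProfile(
        positions=profile.positions,
        reactivities=rea / ref_mean,
        sem=None if profile.sem is None else profile.sem / ref_mean,
        annotations=profile.annotations,
        condition_label=profile.condition_label,
        normalized=True,
        n_floored=n_floored,
    )


@dataclass(frozen=True)
class ControlCheck:
    """Internal-control diagnostic: mean 5'-hairpin-loop reactivity relative
    to the 3' reference mean, with a pass/warn flag."""

    ratio: float
    passed: bool
    band: tuple[float, float]


def control_check(profile: ShapeProfile, warn_band: tuple[float, float] = (0.8, 1.2)) -> ControlCheck:
    """Ratio of the mean control-loop reactivity to the reference mean.

    On a normalized profile the reference mean is 1 by construction, so
    the ratio equals the mean control reactivity.
    """
    ctrl = profile.mask(CONTROL_FLAG)
    ref = profile.mask(REFERENCE_FLAG)
    if not np.any(ctrl) or not np.any(ref):
        raise ValueError("profile lacks control and/or reference annotations")
    ratio = float(profile.reactivities[ctrl].mean() / profile.reactivities[ref].mean())
    passed = warn_band[0] <= ratio <= warn_band[1]
    if not passed:
        warnings.warn(
            f"control/reference reactivity ratio {ratio:.3f} outside {warn_band}",
            stacklevel=2,
        )
    return ControlCheck(ratio=ratio, passed=passed, band=warn_band)


@dataclass(frozen=True)
class DifferentialProfile:
    """Position-wise reactivity difference between two conditions with
    quadrature-propagated errors; artifact positions carry a caveat flag."""

    positions: np.ndarray
    delta: np.ndarray
    sigma: np.ndarray
    caveat: np.ndarray  # True where rt_stop_artifact applies
    label_a: str
    label_b: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "delta": self.delta,
                "sigma": self.sigma,
                "caveat_rt_stop": self.caveat,
                "condition_a": self.label_a,
                "condition_b": self.label_b,
            }
        )


def differential(a: ShapeProfile, b: ShapeProfile) -> DifferentialProfile:
    """Per-position difference a - b of two normalized profiles.

    sigma_i = sqrt(sem_a^2 + sem_b^2); both profiles must be normalized
    and cover the same positions.
    """
    _check_matched(a, b)
    if not (a.normalized and b.normalized):
        raise ValueError("differential requires normalized profiles")
    if a.sem is None or b.sem is None:
        raise ValueError("differential requires aggregated profiles with sem")
    caveat = a.mask(ARTIFACT_FLAG) | b.mask(ARTIFACT_FLAG)
    return DifferentialProfile(
        positions=a.positions.copy(),
        delta=a.reactivities - b.reactivities,
        sigma=np.sqrt(a.sem**2 + b.sem**2),
        caveat=caveat,
        label_a=a.condition_label,
        label_b=b.condition_label,
    )
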