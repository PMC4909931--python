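"""Imino chemical-shift classification by base-pair context.

RNA imino groups (G N1-H1, U N3-H3) have (1H, 15N) chemical shifts that
cluster by base-pairing context — Watson-Crick G-C or A-U, G-U wobble,
sheared G-A, unpaired.  Each context is summarised as an ellipse centred
on the mean shift with semi-axes of twice the standard deviation along
each dimension; a shift belongs to a context when its normalized elliptic
distance

    d = sqrt( ((h - mean_h)/(2 sd_h))^2 + ((n - mean_n)/(2 sd_n))^2 )

is at most 1.  Because the 15N shift of a fitted excited state follows
from omega_ES = omega_GS + dw, a proposed base-pairing transition can be
scored for consistency against the destination context's 15N band.

The packaged ellipse table is a synthetic illustration with typical
literature-scale values; it is editable and analyses should substitute
their own curated reference where fidelity matters.  Only the 15N axis is
used for transition scoring, since dispersion-fitted dw here is 15N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "IminoShift",
    "PairContextEllipse",
    "ContextMatch",
    "TransitionReport",
    "ellipse_distance",
    "classify_shift",
    "transition_consistency",
    "load_reference_ellipses",
    "read_ellipse_table",
]

_H_WINDOW = (9.0, 16.0)
_N_WINDOW = (135.0, 165.0)


@dataclass(frozen=True)
class IminoShift:
    """One imino group's (1H, 15N) chemical shift."""

    residue_label: str
    base_type: str  # "G" or "U"
    h_shift_ppm: float
    n_shift_ppm: float

    def __post_init__(self) -> None:
        if self.base_type not in ("G", "U"):
            raise ValueError(f"base_type must be G or U, got {self.base_type!r}")
        if not _H_WINDOW[0] <= self.h_shift_ppm <= _H_WINDOW[1]:
            warnings.warn(
                f"{self.residue_label}: 1H shift {self.h_shift_ppm} ppm outside the "
                f"typical imino window {_H_WINDOW}",
                stacklevel=2,
            )
        if not _N_WINDOW[0] <= self.n_shift_ppm <= _N_WINDOW[1]:
            warnings.warn(
                f"{self.residue_label}: 15N shift {self.n_shift_ppm} ppm outside the "
                f"typical imino window {_N_WINDOW}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PairContextEllipse:
    """A base-pair context summarised by mean +/- 2 s.d. in (1H, 15N)."""

    context_label: str
    base_type: str
    mean_h: float
    sd_h: float
    mean_n: float
    sd_n: float

    def __post_init__(self) -> None:
        if self.sd_h <= 0 or self.sd_n <= 0:
            raise ValueError(f"{self.context_label}: standard deviations must be positive")


def ellipse_distance(shift: IminoShift, ellipse: PairContextEllipse) -> float:
    """Normalized elliptic distance; membership iff <= 1."""
    return math.sqrt(
        ((shift.h_shift_ppm - ellipse.mean_h) / (2.0 * ellipse.sd_h)) ** 2
        + ((shift.n_shift_ppm - ellipse.mean_n) / (2.0 * ellipse.sd_n)) ** 2
    )


@dataclass(frozen=True)
class ContextMatch:
    context_label: str
    distance: float
    member: bool
    ambiguous: bool = False


def classify_shift(shift: IminoShift, reference) -> tuple[list[ContextMatch], list[str]]:
    """Rank compatible contexts by elliptic distance.

    Returns (matches in ascending distance, notes).  Contexts whose base
    type is incompatible with the shift's base are excluded with a note.
    Exact distance ties are broken alphabetically by context label and
    flagged ambiguous.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference ellipse set")
    notes = []
    rows = []
    for ell in reference:
        if ell.base_type != shift.base_type:
            notes.append(
                f"excluded {ell.context_label}: base type {ell.base_type} incompatible "
                f"with {shift.base_type} shift"
            )
            continue
        rows.append((ellipse_distance(shift, ell), ell.context_label))
    rows.sort(key=lambda r: (r[0], r[1]))
    matches = []
    for i, (dist, label) in enumerate(rows):
        tied = any(j != i and abs(rows[j][0] - dist) < 1e-12 for j in range(len(rows)))
        matches.append(ContextMatch(label, dist, member=dist <= 1.0, ambiguous=tied))
    return matches, notes


@dataclass(frozen=True)
class TransitionReport:
    """Consistency of a fitted 15N dw with a proposed context transition."""

    omega_gs_ppm: float
    omega_es_ppm: float
    dw_ppm: float
    context_from: str
    context_to: str
    within_destination_band: bool
    sign_matches: bool

    @property
    def consistent(self) -> bool:
        return self.within_destination_band and self.sign_matches


def _find_context(reference, label: str) -> PairContextEllipse:
    for ell in reference:
        if ell.context_label == label:
            return ell
    raise KeyError(f"context {label!r} not in reference set")


def transition_consistency(
    gs_shift_n_ppm: float,
    fitted_dw_ppm: float,
    proposed: tuple[str, str],
    reference,
) -> TransitionReport:
    """Score a proposed GS->ES base-pairing transition against fitted dw.

    Computes omega_ES = omega_GS + dw, then checks (i) whether omega_ES
    falls within the destination context's 15N band (|omega_ES - mean_n|
    <= 2 sd_n) and (ii) whether the sign of dw matches the direction
    between the two context centres.  A null transition (dw = 0, same
    context) counts as sign-consistent.
    """
    reference = list(reference)
    ctx_from = _find_context(reference, proposed[0])
    ctx_to = _find_context(reference, proposed[1])
    omega_es = gs_shift_n_ppm + fitted_dw_ppm
    within = abs(omega_es - ctx_to.mean_n) <= 2.0 * ctx_to.sd_n
    direction = ctx_to.mean_n - ctx_from.mean_n
    if fitted_dw_ppm == 0.0 and proposed[0] == proposed[1]:
        sign_ok = True
    else:
        sign_ok = fitted_dw_ppm * direction > 0
    return TransitionReport(
        omega_gs_ppm=gs_shift_n_ppm,
        omega_es_ppm=omega_es,
        dw_ppm=fitted_dw_ppm,
        context_from=proposed[0],
        context_to=proposed[1],
        within_destination_band=within,
        sign_matches=sign_ok,
    )


def _ellipses_from_frame(df: pd.DataFrame) -> list[PairContextEllipse]:
    required = {"context", "base_type", "mean_h_ppm", "sd_h_ppm", "mean_n_ppm", "sd_n_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ellipse table missing columns: {sorted(missing)}")
    return [
        PairContextEllipse(
            context_label=str(row.context),
            base_type=str(row.base_type),
            mean_h=float(row.mean_h_ppm),
            sd_h=float(row.sd_h_ppm),
            mean_n=float(row.mean_n_ppm),
            sd_n=float(row.sd_n_ppm),
        )
        for row in df.itertuples()
    ]


def read_ellipse_table(path) -> list[PairContextEllipse]:
    """Read a tab-delimited context-ellipse table (columns: context,
    base_type, mean_h_ppm, sd_h_ppm, mean_n_ppm, sd_n_ppm)."""
    return _ellipses_from_frame(pd.read_csv(path, sep="\t"))


def load_reference_ellipses() -> list[PairContextEllipse]:
    """Load the packaged illustrative context-ellipse table."""
    with resources.files("spinex.data").joinpath("imino_context_ellipses.tsv").open() as fh:
        return _ellipses_from_frame(pd.read_csv(fh, sep="\t"))
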