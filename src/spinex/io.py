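"""Readers and writers for every table the pipeline consumes or emits.

All tables are tab-delimited plain text (upstream spectral processing is
out of scope; the analysis starts at peak intensities).  Column
conventions (see also docs/methods.md):

decay table:   residue, power_hz, offset_hz, delay_s, intensity
               [, intensity_sigma]  — offsets signed, powers unsigned,
               delays in seconds
r1rho table:   residue, power_hz, offset_hz, r1rho, sigma, i0
shape table:   position, reactivity, sem, flags (comma-joined), condition
fit report:    YAML with shared parameters +/- sigma, per-residue rows,
               chi2, seed and tool version, plus a rendered text table.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ExchangeParams, SpinLockCondition
from .decay import DecayCurve, R1rhoPoint
from .globalfit import GlobalFitResult, RDProfile
from .shape import ShapeProfile

__all__ = [
    "read_decay_table",
    "write_decay_table",
    "read_r1rho_table",
    "write_r1rho_table",
    "read_shape_table",
    "write_shape_table",
    "write_fit_report",
    "read_fit_report",
]

_DECAY_COLS = ["residue", "power_hz", "offset_hz", "delay_s", "intensity"]


class TableFormatError(ValueError):
    """Malformed table content, reported with 1-based file line numbers."""


def write_decay_table(curves, path) -> None:
    rows = []
    for c in curves:
        sig = c.intensity_sigma
        for i, (t, inten) in enumerate(zip(c.delays_s, c.intensities)):
            row = {
                "residue": c.residue_label,
                "power_hz": c.condition.spinlock_power_hz,
                "offset_hz": c.condition.carrier_offset_hz,
                "delay_s": t,
                "intensity": inten,
            }
            if sig is not None:
                row["intensity_sigma"] = sig[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_decay_table(path) -> list[DecayCurve]:
    """Parse a decay table into DecayCurve objects grouped by
    (residue, power, offset); validates as it goes and reports offending
    1-based line numbers."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_DECAY_COLS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    # header is line 1, first data row line 2
    lines = df.index + 2
    for col in ("power_hz", "offset_hz", "delay_s", "intensity"):
        bad = ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            raise TableFormatError(f"{path}: non-numeric {col} at line {lines[bad][0]}")
    neg = df["delay_s"] < 0
    if neg.any():
        raise TableFormatError(f"{path}: negative delay at line {lines[neg][0]}")
    dup = df.duplicated(subset=["residue", "power_hz", "offset_hz", "delay_s"])
    if dup.any():
        raise TableFormatError(f"{path}: duplicate (residue, condition, delay) row at line {lines[dup][0]}")

    has_sigma = "intensity_sigma" in df.columns
    curves = []
    for (res, power, offset), grp in df.groupby(["residue", "power_hz", "offset_hz"], sort=True):
        grp = grp.sort_values("delay_s")
        cond = SpinLockCondition(
            spinlock_power_hz=float(power),
            carrier_offset_hz=float(offset),
            duration_grid_s=tuple(grp["delay_s"]),
        )
        curves.append(
            DecayCurve(
                residue_label=str(res),
                condition=cond,
                delays_s=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                intensity_sigma=grp["intensity_sigma"].to_numpy() if has_sigma else None,
            )
        )
    return curves


def write_r1rho_table(profiles, path) -> None:
    rows = [
        {
            "residue": prof.residue_label,
            "power_hz": p.condition.spinlock_power_hz,
            "offset_hz": p.condition.carrier_offset_hz,
            "r1rho": p.r1rho,
            "sigma": p.sigma,
            "i0": p.i0,
        }
        for prof in profiles
        for p in prof.points
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_r1rho_table(path) -> list[RDProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"residue", "power_hz", "offset_hz", "r1rho", "sigma"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    by_res = defaultdict(list)
    for row in df.itertuples():
        cond = SpinLockCondition(
            spinlock_power_hz=float(row.power_hz),
            carrier_offset_hz=float(row.offset_hz),
        )
        by_res[str(row.residue)].append(
            R1rhoPoint(
                condition=cond,
                r1rho=float(row.r1rho),
                sigma=float(row.sigma),
                i0=float(getattr(row, "i0", 0.0)),
            )
        )
    return [RDProfile(residue_label=r, points=tuple(pts)) for r, pts in sorted(by_res.items())]


def write_shape_table(profiles, path) -> None:
    # the replicate column keeps same-condition replicates apart on re-read
    pd.concat([p.to_frame(replicate=i) for i, p in enumerate(profiles)]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_shape_table(path) -> list[ShapeProfile]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan"])
    required = {"position", "reactivity", "sem", "flags", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    profiles = []
    for (label, _), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("position")
        sems = pd.to_numeric(grp["sem"], errors="coerce").to_numpy()
        profiles.append(
            ShapeProfile(
                positions=grp["position"].to_numpy(dtype=int),
                reactivities=grp["reactivity"].to_numpy(dtype=float),
                sem=None if np.all(np.isnan(sems)) else sems,
                annotations=[
                    frozenset(f for f in str(s).split(",") if f) for s in grp["flags"]
                ],
                condition_label=str(label),
            )
        )
    return profiles


def write_fit_report(result: GlobalFitResult, path) -> None:
    """Emit a structured, re-readable fit report (YAML) that also contains
    a human-readable table rendering."""
    per_residue = {}
    for label, pars in result.per_residue.items():
        row = dict(pars)
        if result.per_residue_sigma is not None:
            row.update({f"{k}_sigma": v for k, v in result.per_residue_sigma[label].items()})
        per_residue[label] = row
    doc = {
        "tool_version": __version__,
        "shared": {
            "p_minor": result.exchange.p_minor,
            "k_ex": result.exchange.k_ex,
            **(
                {f"{k}_sigma": v for k, v in result.exchange_sigma.items()}
                if result.exchange_sigma is not None
                else {}
            ),
        },
        "per_residue": per_residue,
        "chi2": result.chi2,
        "n_points": result.n_points,
        "n_free_params": result.n_free_params,
        "reduced_chi2": result.reduced_chi2,
        "flags": list(result.flags),
        "seed_used": result.seed_used,
    }
    lines = [
        f"{'residue':<10}{'R1 (s-1)':>10}{'R2 (s-1)':>10}{'dw (ppm)':>10}",
    ]
    for label, pars in result.per_residue.items():
        lines.append(
            f"{label:<10}{pars['r1']:>10.3f}{pars['r2']:>10.3f}{pars['dw_ppm']:>10.3f}"
        )
    doc["table"] = "\n".join(lines)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_fit_report(path) -> GlobalFitResult:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shared = doc["shared"]
    per_residue = {}
    per_residue_sigma = {}
    for label, row in doc["per_residue"].items():
        per_residue[label] = {k: row[k] for k in ("r1", "r2", "dw_ppm")}
        sig = {k[: -len("_sigma")]: v for k, v in row.items() if k.endswith("_sigma")}
        if sig:
            per_residue_sigma[label] = sig
    result = GlobalFitResult(
        exchange=ExchangeParams(p_minor=shared["p_minor"], k_ex=shared["k_ex"]),
        per_residue=per_residue,
        chi2=doc["chi2"],
        n_points=doc["n_points"],
        n_free_params=doc["n_free_params"],
        flags=list(doc.get("flags", [])),
        seed_used=doc.get("seed_used"),
    )
    if "p_minor_sigma" in shared:
        result.exchange_sigma = {
            "p_minor": shared["p_minor_sigma"],
            "k_ex": shared["k_ex_sigma"],
        }
    if per_residue_sigma:
        result.per_residue_sigma = per_residue_sigma
    return result
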