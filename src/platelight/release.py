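"""Calcein-release analysis for ROS-sensitive liposome assays.

Calcein encapsulated at self-quenching concentration is weakly fluorescent;
photooxidation of unsaturated lipids releases and dilutes it, de-quenching
the dye.  Release is quantified against two on-plate controls:

    CR% = (F - F0) / (F100 - F0) * 100

where ``F`` is the sample fluorescence, ``F0`` the background of the cold
(never-illuminated) control and ``F100`` the maximum after Triton X-100
lysis.  CR% is returned unclamped — values outside [0, 100] are a quality
signal about the controls, so they are flagged rather than truncated.

The module also carries the surrounding bookkeeping of a release screen:
replicate statistics, release-vs-dose curves with attached light dose,
an optional first-order saturation fit CR(H) = CR_max*(1 - exp(-k*H)),
dose-to-half-max summaries, encapsulation efficiency and DLS stability
deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ROLES",
    "calcein_release_percent",
    "summarize_replicates",
    "ReleaseCurve",
    "build_release_curves",
    "dose_to_half_max",
    "pool_curves",
    "fit_release_kinetics",
    "KineticFit",
    "encapsulation_efficiency",
    "dls_delta",
    "read_fluorescence_table",
    "write_fluorescence_table",
    "curves_to_frame",
]

ROLES = ("sample", "cold_control", "triton_max", "dark_control")

TABLE_HEADER = "# platelight release-table v1"
#: columns of the plate-reader exchange format
TABLE_COLUMNS = [
    "well",
    "time_s",
    "fluorescence",
    "role",
    "formulation",
    "irradiance_mW_cm2",
]


def calcein_release_percent(F: float, F0: float, F100: float) -> float:
    """Percentage of released calcein for one reading.

    Raises if the controls are degenerate (F100 <= F0).  The result is not
    clamped; use :func:`out_of_range` to flag readings outside [0, 100].
    """
    if F100 <= F0:
        raise ValueError(
            f"degenerate controls: F100={F100:g} must exceed F0={F0:g}"
        )
    if F < 0:
        raise ValueError("fluorescence cannot be negative")
    return (F - F0) / (F100 - F0) * 100.0


def out_of_range(cr_percent: float) -> bool:
    return cr_percent < 0.0 or cr_percent > 100.0


def summarize_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample sd, n) of replicate release percentages.

    Sample standard deviation (n-1 denominator); a single replicate yields
    sd = 0.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return mean, sd, int(vals.size)


@dataclass
class ReleaseCurve:
    """Release-vs-dose trajectory of one formulation.

    ``points`` has columns time_s, dose_J_cm2, mean_cr_percent,
    sd_cr_percent, n, any_out_of_range.
    """

    formulation: str
    irradiance_mW_cm2: float
    points: pd.DataFrame
    dark: bool = False

    @property
    def max_release(self) -> float:
        return float(self.points["mean_cr_percent"].max())


def _control_level(group: pd.DataFrame, role: str, time_s: float) -> float:
    """Mean control fluorescence at the matching timepoint.

    Controls are matched per timepoint; when a timepoint has no control of
    its own, all controls of that role in the group are pooled.  (Whether
    controls are per-timepoint or per-plate constants is an assay-design
    choice; per-matching-time is used here and recorded in curve metadata.)
    """
    ctl = group[group["role"] == role]
    if ctl.empty:
        raise ValueError(
            f"group {group['formulation'].iat[0]!r} lacks {role} controls"
        )
    at_t = ctl[np.isclose(ctl["time_s"].to_numpy(dtype=float), time_s)]
    pool = at_t if not at_t.empty else ctl
    return float(pool["fluorescence"].mean())


def build_release_curves(records: pd.DataFrame) -> list[ReleaseCurve]:
    """Group a plate-reader table into per-formulation release curves.

    Dose is attached from the formulation's irradiance, H = E*t/1000.
    Dark-control wells are summarized into their own curve (``dark=True``,
    dose 0 since they are shielded) and never mixed into illuminated ones.
    """
    missing = [c for c in TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"fluorescence table missing columns {missing}")
    bad_roles = set(records["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}")

    curves: list[ReleaseCurve] = []
    for (formulation, E), group in records.groupby(
        ["formulation", "irradiance_mW_cm2"], sort=True
    ):
        for role, dark in (("sample", False), ("dark_control", True)):
            wells = group[group["role"] == role]
            if wells.empty:
                continue
            rows = []
            for t, reps in wells.groupby("time_s", sort=True):
                F0 = _control_level(group, "cold_control", t)
                F100 = _control_level(group, "triton_max", t)
                cr = [
                    calcein_release_percent(f, F0, F100)
                    for f in reps["fluorescence"]
                ]
                mean, sd, n = summarize_replicates(cr)
                rows.append(
                    {
                        "time_s": float(t),
                        "dose_J_cm2": 0.0 if dark else float(E) * float(t) / 1000.0,
                        "mean_cr_percent": mean,
                        "sd_cr_percent": sd,
                        "n": n,
                        "any_out_of_range": any(out_of_range(v) for v in cr),
                    }
                )
            curves.append(
                ReleaseCurve(
                    formulation=str(formulation),
                    irradiance_mW_cm2=float(E),
                    points=pd.DataFrame(rows),
                    dark=dark,
                )
            )
    return curves


def dose_to_half_max(curve: ReleaseCurve) -> float | None:
    """Dose at the first crossing of 50% of the curve's own maximum.

    Linear interpolation between bracketing points; ``None`` when the curve
    never crosses (flat or all-zero curves).
    """
    pts = curve.points.sort_values("dose_J_cm2")
    doses = pts["dose_J_cm2"].to_numpy(dtype=float)
    cr = pts["mean_cr_percent"].to_numpy(dtype=float)
    if cr.size == 0 or cr.max() <= 0:
        return None
    half = cr.max() / 2.0
    if cr[0] >= half:
        return float(doses[0])
    for i in range(1, cr.size):
        if cr[i] >= half:
            d0, d1, c0, c1 = doses[i - 1], doses[i], cr[i - 1], cr[i]
            if c1 == c0:
                return float(d1)
            return float(d0 + (half - c0) * (d1 - d0) / (c1 - c0))
    return None


def pool_curves(curves: Sequence[ReleaseCurve]) -> ReleaseCurve:
    """Merge same-formulation curves measured at different irradiances.

    In a dose-driven release model CR depends on H alone, so points taken at
    different irradiances are one curve in dose; pooling them widens the dose
    range and is what identifies the saturation plateau when a low-irradiance
    series alone never reaches it.
    """
    if not curves:
        raise ValueError("no curves to pool")
    labels = {c.formulation for c in curves}
    if len(labels) != 1:
        raise ValueError(f"cannot pool different formulations {sorted(labels)}")
    if any(c.dark for c in curves):
        raise ValueError("dark-control curves cannot be pooled with illuminated ones")
    pts = pd.concat([c.points for c in curves], ignore_index=True)
    pts = pts.sort_values("dose_J_cm2", ignore_index=True)
    return ReleaseCurve(curves[0].formulation, float("nan"), pts)


@dataclass(frozen=True)
class KineticFit:
    """First-order saturation fit CR(H) = CR_max*(1 - exp(-k*H))."""

    cr_max_percent: float
    cr_max_se: float
    k_per_J_cm2: float
    k_se: float


def fit_release_kinetics(curve: ReleaseCurve) -> KineticFit:
    """Fit the saturation model to a curve's mean points.

    A convenience summary of screen output, not a mechanistic claim: the
    true photorelease kinetics need not be first order in dose.
    """
    pts = curve.points
    H = pts["dose_J_cm2"].to_numpy(dtype=float)
    cr = pts["mean_cr_percent"].to_numpy(dtype=float)
    if H.size < 3:
        raise ValueError("need at least 3 dose points for a kinetic fit")

    def model(h, cr_max, k):
        return cr_max * (1.0 - np.exp(-k * h))

    cr_guess = max(cr.max(), 1.0)
    # crude rate guess from the first nonzero-dose point
    pos = H > 0
    k_guess = 0.1
    if pos.any():
        h1 = H[pos].min()
        c1 = float(cr[H == h1][0])
        frac = min(max(c1 / cr_guess, 1e-3), 0.999)
        k_guess = -math.log(1.0 - frac) / h1
    popt, pcov = curve_fit(
        model, H, cr, p0=[cr_guess, k_guess],
        bounds=([0.0, 0.0], [200.0, np.inf]), maxfev=10000,
    )
    se = np.sqrt(np.diag(pcov))
    return KineticFit(float(popt[0]), float(se[0]), float(popt[1]), float(se[1]))


def encapsulation_efficiency(feed_mol: float, encapsulated_mol: float) -> float:
    """EE% = encapsulated / feed * 100."""
    if feed_mol <= 0:
        raise ValueError("feed amount must be positive")
    if not (0 <= encapsulated_mol <= feed_mol):
        raise ValueError("encapsulated amount must lie in [0, feed]")
    return encapsulated_mol / feed_mol * 100.0


def dls_delta(records: pd.DataFrame) -> pd.DataFrame:
    """Per-formulation max |Δsize| and max |ΔPDI| vs the t=0 baseline.

    ``records`` columns: formulation, time_s, size_nm, pdi.  A formulation
    without a t=0 record is an error.
    """
    out = []
    for formulation, grp in records.groupby("formulation", sort=True):
        base = grp[grp["time_s"] == 0]
        if base.empty:
            raise ValueError(f"formulation {formulation!r} has no t=0 baseline")
        size0 = float(base["size_nm"].iloc[0])
        pdi0 = float(base["pdi"].iloc[0])
        out.append(
            {
                "formulation": formulation,
                "max_abs_dsize_nm": float((grp["size_nm"] - size0).abs().max()),
                "max_abs_dpdi": float((grp["pdi"] - pdi0).abs().max()),
            }
        )
    return pd.DataFrame(out)


# -- I/O --------------------------------------------------------------------


def read_fluorescence_table(path: str | Path) -> pd.DataFrame:
    """Read the versioned plate-reader CSV exchange format."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# platelight release-table"):
        raise ValueError(f"{path} lacks the release-table header line")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing columns {missing}")
    return df


def write_fluorescence_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TABLE_HEADER + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def curves_to_frame(curves: Sequence[ReleaseCurve]) -> pd.DataFrame:
    """Tidy long-format table of a set of release curves."""
    frames = []
    for c in curves:
        pts = c.points.copy()
        pts.insert(0, "formulation", c.formulation)
        pts.insert(1, "irradiance_mW_cm2", c.irradiance_mW_cm2)
        pts.insert(2, "dark", c.dark)
        frames.append(pts)
    return pd.concat(frames, ignore_index=True)
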