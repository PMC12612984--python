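"""Relative singlet-oxygen quantum-yield estimation.

The singlet-oxygen quantum yield Φ of a photosensitizer is estimated by the
relative slope method: a dilution series of the sample and of a reference
compound of known yield are excited at the same wavelength, the 1270 nm
singlet-oxygen phosphorescence is integrated over a fixed window
(1220-1350 nm by default), and the integrated intensity is regressed on the
absorbance at the excitation wavelength.  With slope S for each series,

    Φ_sample = Φ_ref * S_sample / S_ref

The default reference constant is unsubstituted zinc phthalocyanine in
toluene, Φ_ref = 0.58.  Uncertainty is propagated to first order from the
two slope standard errors.  Slopes are fitted by ordinary least squares with
an intercept by default (scattering and detector background produce offsets);
a through-origin fit is available via ``through_origin=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHI_REF_ZNPC_TOLUENE",
    "EMISSION_WINDOW_NM",
    "QYSeries",
    "SlopeFit",
    "QYResult",
    "integrate_emission",
    "fit_slope",
    "quantum_yield",
    "read_series_table",
    "series_from_frame",
]

#: Φ of unsubstituted ZnPc in toluene, the conventional red-region reference.
PHI_REF_ZNPC_TOLUENE = 0.58
#: integration window for singlet-oxygen phosphorescence (max at 1270 nm)
EMISSION_WINDOW_NM = (1220.0, 1350.0)


@dataclass(frozen=True)
class QYSeries:
    """Absorbance-vs-integrated-emission points for one compound."""

    label: str
    absorbance: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.absorbance) != len(self.intensity):
            raise ValueError("absorbance and intensity lengths differ")
        if len(self.absorbance) < 2:
            raise ValueError("need at least 2 points per series")
        if min(self.absorbance) < 0 or min(self.intensity) < 0:
            raise ValueError("absorbance and intensity must be non-negative")
        if len(set(self.absorbance)) < 2:
            raise ValueError("absorbances all equal; slope not identifiable")


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    slope_se: float
    intercept: float
    through_origin: bool


@dataclass(frozen=True)
class QYResult:
    phi: float
    phi_se: float
    sample_label: str
    reference_label: str
    phi_ref: float
    warning_above_unity: bool


def integrate_emission(
    wavelength_nm: Sequence[float],
    intensity: Sequence[float],
    lo: float = EMISSION_WINDOW_NM[0],
    hi: float = EMISSION_WINDOW_NM[1],
) -> float:
    """Trapezoidal integral of an emission spectrum over [lo, hi] nm.

    The spectrum must be sorted in wavelength and cover the window; the
    window edges are included by linear interpolation.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be sorted and distinct")
    if lo >= hi:
        raise ValueError("empty integration window")
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"spectrum [{wl[0]:g}, {wl[-1]:g}] nm does not cover "
            f"the window [{lo:g}, {hi:g}] nm"
        )
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, wl, inten)], inten[inside], [np.interp(hi, wl, inten)])
    )
    return float(np.trapezoid(ys, xs))


def fit_slope(series: QYSeries, through_origin: bool = False) -> SlopeFit:
    """OLS slope of integrated intensity on absorbance.

    Intercept included by default; ``through_origin`` forces a zero
    intercept (slope = Σxy/Σx² with the matching 1-parameter standard
    error).  Exact on collinear points (se = 0).
    """
    x = np.asarray(series.absorbance, dtype=float)
    y = np.asarray(series.intensity, dtype=float)
    if through_origin:
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise ValueError("all absorbances zero; slope not identifiable")
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        dof = x.size - 1
        se = math.sqrt(float(np.dot(resid, resid)) / dof / sxx) if dof > 0 else 0.0
        return SlopeFit(slope, se, 0.0, True)
    res = stats.linregress(x, y)
    se = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return SlopeFit(float(res.slope), se, float(res.intercept), False)


def quantum_yield(
    sample: QYSeries,
    reference: QYSeries,
    phi_ref: float = PHI_REF_ZNPC_TOLUENE,
    through_origin: bool = False,
) -> QYResult:
    """Φ_sample = Φ_ref * S_sample / S_ref with first-order error propagation.

    Both series must have been measured at the same excitation wavelength
    and detector gain — that matching is asserted by experiment metadata,
    not enforced here.  A yield above 1 is physically impossible and sets a
    warning flag (it is reported as computed, as a QC signal).
    """
    if phi_ref <= 0:
        raise ValueError("phi_ref must be positive")
    fit_s = fit_slope(sample, through_origin=through_origin)
    fit_r = fit_slope(reference, through_origin=through_origin)
    if fit_r.slope <= 0:
        raise ValueError(
            f"reference slope must be positive (got {fit_r.slope:g})"
        )
    phi = phi_ref * fit_s.slope / fit_r.slope
    rel_var = 0.0
    if fit_s.slope != 0:
        rel_var += (fit_s.slope_se / fit_s.slope) ** 2
    rel_var += (fit_r.slope_se / fit_r.slope) ** 2
    phi_se = abs(phi) * math.sqrt(rel_var)
    return QYResult(
        phi=phi,
        phi_se=phi_se,
        sample_label=sample.label,
        reference_label=reference.label,
        phi_ref=phi_ref,
        warning_above_unity=phi > 1.0,
    )


# -- I/O --------------------------------------------------------------------

SERIES_HEADER = "# platelight qy-series v1"


def read_series_table(path: str | Path) -> dict[str, QYSeries]:
    """Read a versioned CSV of (label, absorbance, integrated_intensity)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# platelight qy-series"):
        raise ValueError(f"{path} lacks the qy-series header line")
    df = pd.read_csv(path, comment="#")
    need = ["label", "absorbance", "integrated_intensity"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing columns {missing}")
    return series_from_frame(df)


def series_from_frame(df: pd.DataFrame) -> dict[str, QYSeries]:
    out: dict[str, QYSeries] = {}
    for label, grp in df.groupby("label", sort=True):
        out[str(label)] = QYSeries(
            label=str(label),
            absorbance=tuple(float(a) for a in grp["absorbance"]),
            intensity=tuple(float(i) for i in grp["integrated_intensity"]),
        )
    return out


def write_series_table(series: Sequence[QYSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for a, i in zip(s.absorbance, s.intensity):
            rows.append({"label": s.label, "absorbance": a,
                         "integrated_intensity": i})
    with open(path, "w") as fh:
        fh.write(SERIES_HEADER + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")
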