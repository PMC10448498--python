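"""Competitive-assay statistics: four-parameter logistic dose response.

In the competitive format, free analyte (biotin) blocks the streptavidin
sites of one nanoparticle conjugate, suppressing the formation of two-color
bioaffinity clusters; the double-spot count per frame (DSC) therefore falls
with analyte concentration.  The dose response is modeled by the
four-parameter logistic (4PL)

    DSC([B]) = DSC_bg + (DSC_max - DSC_bg) / (1 + ([B]/IC50)^S)

with asymptotes DSC_max (zero analyte) and DSC_bg (saturation), midpoint
IC50, and slope S at the inflection point.  The detection threshold is
DSC_LOD = DSC_max - k * SD(DSC at zero analyte) with k = 3.3 by default, and
the assay LOD is the inverted 4PL evaluated at DSC_LOD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "AssayLimits",
    "four_pl",
    "fit_four_pl",
    "dsc_lod",
    "invert_four_pl",
    "compute_limits",
    "assay_report",
]


@dataclass
class DoseResponse:
    """Dose-response table: analyte levels (mol/L, zero included) with
    per-level DSC means and replicate SDs."""

    biotin_mol_per_L: np.ndarray
    dsc_mean: np.ndarray
    dsc_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.biotin_mol_per_L = np.asarray(self.biotin_mol_per_L, dtype=float)
        self.dsc_mean = np.asarray(self.dsc_mean, dtype=float)
        if self.dsc_sd is not None:
            self.dsc_sd = np.asarray(self.dsc_sd, dtype=float)
        if self.biotin_mol_per_L.shape != self.dsc_mean.shape:
            raise ValueError("level and DSC arrays must align")
        if np.any(self.biotin_mol_per_L < 0) or np.any(self.dsc_mean < 0):
            raise ValueError("levels and DSC values must be nonnegative")
        if self.biotin_mol_per_L.size < 4:
            raise ValueError("need at least 4 levels for a 4-parameter fit")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponse":
        sd = df["dsc_sd"].to_numpy() if "dsc_sd" in df else None
        return cls(df["biotin_mol_per_L"].to_numpy(),
                   df["dsc_mean"].to_numpy(), sd)


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with covariance and residual scale."""

    dsc_max: float
    dsc_bg: float
    ic50_mol_per_L: float
    slope: float
    covariance: np.ndarray | None = None
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dsc_max > self.dsc_bg >= 0):
            raise ValueError("need DSC_max > DSC_bg >= 0")
        if self.ic50_mol_per_L <= 0 or self.slope <= 0:
            raise ValueError("IC50 and slope must be positive")


def four_pl(biotin_mol_per_L, fit: FourPLFit):
    """Evaluate the 4PL dose response; exactly DSC_max at zero analyte."""
    b = np.asarray(biotin_mol_per_L, dtype=float)
    if np.any(b < 0):
        raise ValueError("analyte concentration must be nonnegative")
    with np.errstate(divide="ignore"):
        ratio = np.where(b > 0, (b / fit.ic50_mol_per_L) ** fit.slope, 0.0)
    out = fit.dsc_bg + (fit.dsc_max - fit.dsc_bg) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries optimizer diagnostics."""


def fit_four_pl(data: DoseResponse) -> FourPLFit:
    """Nonlinear least-squares 4PL fit on linear concentration.

    Initialization: DSC_max = max level mean, DSC_bg = min level mean,
    IC50 = level nearest the midpoint response, S = 1.  Per-level 1/SD^2
    weighting when replicate SDs are present, uniform otherwise; positivity
    of all parameters is enforced by bounds.
    """
    b = data.biotin_mol_per_L
    y = data.dsc_mean
    ymax, ymin = float(y.max()), float(y.min())
    mid = (ymax + ymin) / 2.0
    pos = b[b > 0]
    if pos.size == 0:
        raise FitError("need nonzero analyte levels to fit an IC50")
    ic50_0 = float(pos[np.argmin(np.abs(y[b > 0] - mid))])

    def model(bb, dsc_max, dsc_bg, ic50, s):
        with np.errstate(divide="ignore"):
            ratio = np.where(bb > 0, (bb / ic50) ** s, 0.0)
        return dsc_bg + (dsc_max - dsc_bg) / (1.0 + ratio)

    sigma = None
    if data.dsc_sd is not None:
        sd = np.asarray(data.dsc_sd, dtype=float)
        if np.any(sd > 0):
            sigma = np.maximum(sd, sd[sd > 0].min())
    span = max(ymax - ymin, 1e-12)
    p0 = [ymax, max(ymin, 1e-9), ic50_0, 1.0]
    bounds = ([ymin, 0.0, pos.min() / 1e3, 0.05],
              [ymax + 10 * span, ymax, pos.max() * 1e3, 20.0])
    try:
        popt, pcov = optimize.curve_fit(model, b, y, p0=p0, sigma=sigma,
                                        absolute_sigma=False, bounds=bounds,
                                        maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    resid = y - model(b, *popt)
    dof = max(len(y) - 4, 1)
    fit = FourPLFit(dsc_max=float(popt[0]), dsc_bg=float(popt[1]),
                    ic50_mol_per_L=float(popt[2]), slope=float(popt[3]),
                    covariance=pcov,
                    residual_sd=float(np.sqrt((resid**2).sum() / dof)))
    return fit


def dsc_lod(fit: FourPLFit, sd_zero: float, k: float = 3.3) -> float:
    """DSC detection threshold: DSC_max minus k standard deviations of the
    zero-analyte DSC (k = 3.3 by default, matching the 3.3-sigma blank
    convention of the dilution-series LOD)."""
    if sd_zero < 0:
        raise ValueError("sd_zero must be nonnegative")
    return fit.dsc_max - k * sd_zero


def invert_four_pl(fit: FourPLFit, dsc: float) -> float:
    """Analyte concentration at a given DSC (inverted 4PL).

    Defined on the open interval (DSC_bg, DSC_max); exact inverse of
    :func:`four_pl`.
    """
    if not (fit.dsc_bg < dsc < fit.dsc_max):
        raise ValueError(
            f"DSC {dsc} outside the open response interval "
            f"({fit.dsc_bg}, {fit.dsc_max})")
    span = fit.dsc_max - fit.dsc_bg
    return fit.ic50_mol_per_L * (span / (dsc - fit.dsc_bg) - 1.0) ** (1.0 / fit.slope)


@dataclass
class AssayLimits:
    """Detection limits of a competitive assay."""

    dsc_lod: float
    lod_mol_per_L: float | None
    ic50_mol_per_L: float
    responsive: bool = True


def compute_limits(fit: FourPLFit, sd_zero: float, k: float = 3.3) -> AssayLimits:
    """DSC_LOD and the assay LOD (inverted 4PL at DSC_LOD).

    If DSC_LOD does not fall inside the response interval the assay is
    flagged nonresponsive at this noise level and no molar LOD is reported.
    """
    threshold = dsc_lod(fit, sd_zero, k)
    if threshold <= fit.dsc_bg or threshold >= fit.dsc_max:
        return AssayLimits(dsc_lod=threshold, lod_mol_per_L=None,
                           ic50_mol_per_L=fit.ic50_mol_per_L, responsive=False)
    return AssayLimits(dsc_lod=threshold,
                       lod_mol_per_L=invert_four_pl(fit, threshold),
                       ic50_mol_per_L=fit.ic50_mol_per_L, responsive=True)


def assay_report(data: DoseResponse, fit: FourPLFit, limits: AssayLimits) -> dict:
    """JSON-serializable assay report: parameters, limits, per-level
    residuals and the dose-response table."""
    pred = four_pl(data.biotin_mol_per_L, fit)
    resid = data.dsc_mean - pred
    if data.dsc_sd is not None and np.any(data.dsc_sd > 0):
        sd = np.maximum(data.dsc_sd, data.dsc_sd[data.dsc_sd > 0].min())
        weighted_sq = (resid / sd) ** 2
    else:
        weighted_sq = resid**2
    report = {
        "fit": {
            "dsc_max": fit.dsc_max,
            "dsc_bg": fit.dsc_bg,
            "ic50_mol_per_L": fit.ic50_mol_per_L,
            "slope": fit.slope,
            "residual_sd": fit.residual_sd,
        },
        "limits": {
            "dsc_lod": limits.dsc_lod,
            "lod_mol_per_L": limits.lod_mol_per_L,
            "ic50_mol_per_L": limits.ic50_mol_per_L,
            "responsive": limits.responsive,
        },
        "levels": [
            {
                "biotin_mol_per_L": float(b),
                "dsc_mean": float(y),
                "dsc_sd": (None if data.dsc_sd is None else float(s)),
                "predicted": float(p),
                "residual": float(r),
                "weighted_sq_residual": float(wr),
            }
            for b, y, s, p, r, wr in zip(
                data.biotin_mol_per_L, data.dsc_mean,
                (data.dsc_sd if data.dsc_sd is not None
                 else np.full_like(data.dsc_mean, np.nan)),
                pred, resid, weighted_sq)
        ],
        "objective": float(weighted_sq.sum()),
    }
    json.dumps(report)  # guarantee serializability
    return report
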