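"""Microdialysis probe calibration and non-compartmental analysis.

A microdialysis probe samples unbound drug in tissue fluid, but the
dialysate concentration is only a fraction of the true interstitial
concentration because equilibration across the membrane is incomplete.
That fraction — the relative recovery (RR) — is estimated in vitro by
dialysing a known medium, or in vivo by retrodialysis (spiking the
perfusate and measuring the fractional loss).  Interstitial-fluid
concentrations are then reconstructed as C_ISF = C_dialysate / RR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CalibrationError(ValueError):
    """Invalid probe-calibration input (zero reference, RR out of range)."""


@dataclass(frozen=True)
class DialysisMeasurement:
    """One probe-calibration observation (concentrations in ug/mL)."""

    C_dialysate: float
    C_medium: float | None = None
    C_perfusate: float | None = None
    flow_rate_ul_min: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.C_dialysate < 0:
            raise CalibrationError("dialysate concentration must be non-negative")
        if self.C_medium is None and self.C_perfusate is None:
            raise CalibrationError("need a medium (recovery) or perfusate (delivery) concentration")


def recovery_pct(C_dialysate: float, C_medium: float) -> float:
    """In vitro relative recovery: 100 * C_dialysate / C_medium."""
    if C_medium <= 0:
        raise CalibrationError("medium concentration must be positive")
    return 100.0 * C_dialysate / C_medium


def delivery_pct(C_dialysate: float, C_perfusate: float) -> float:
    """Retrodialysis delivery: 100 * (1 - C_dialysate / C_perfusate)."""
    if C_perfusate <= 0:
        raise CalibrationError("perfusate concentration must be positive")
    return 100.0 * (1.0 - C_dialysate / C_perfusate)


def in_vivo_rr_pct(C_perfusate: float, C_dialysate: float) -> float:
    """In vivo relative recovery by retrodialysis.

    The probe is perfused with drug at a known concentration and the
    fractional loss to the tissue, 100 * (C_perfusate - C_dialysate) /
    C_perfusate, estimates the recovery that applies in the sampling
    direction.
    """
    if C_perfusate <= 0:
        raise CalibrationError("perfusate concentration must be positive")
    return 100.0 * (C_perfusate - C_dialysate) / C_perfusate


def correct_isf(dialysate: np.ndarray, rr_fraction: float) -> np.ndarray:
    """Convert a dialysate trace to free interstitial-fluid concentration.

    C_ISF = C_dialysate / RR, with RR the in vivo relative recovery as a
    fraction in (0, 1].  The returned trace is an unbound concentration.
    """
    if not 0.0 < rr_fraction <= 1.0:
        raise CalibrationError(f"relative recovery must be in (0, 1], got {rr_fraction}")
    return np.asarray(dialysate, dtype=float) / rr_fraction


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental summary of a concentration-time profile.

    ``lambda_z`` is the terminal elimination rate from a log-linear fit;
    ``auc_last`` is the linear-trapezoid AUC to the last quantifiable
    point (plus the C_last/lambda_z tail when extrapolated).  ``mrt`` is
    AUMC/AUC.  ``lambda_z`` and derived quantities are NaN when no
    terminal phase could be fitted (``valid_terminal`` False).
    """

    cmax: float
    tmax: float
    auc_last: float
    aumc_last: float
    mrt: float
    lambda_z: float
    t_half: float
    n_terminal: int
    r2_adj_terminal: float
    extrapolated: bool = False
    auc_inf: float = float("nan")
    valid_terminal: bool = True


def _terminal_fit(t: np.ndarray, c: np.ndarray, k_range=(3, 4, 5)):
    """Log-linear terminal fit over the last 3-5 points after Tmax,
    choosing the window that maximises adjusted R^2."""
    imax = int(np.argmax(c))
    cand_t, cand_c = t[imax + 1:], c[imax + 1:]
    pos = cand_c > 0
    cand_t, cand_c = cand_t[pos], cand_c[pos]
    best = None
    for k in k_range:
        if len(cand_t) < k or k < 3:
            continue
        tt, cc = cand_t[-k:], np.log(cand_c[-k:])
        slope, intercept = np.polyfit(tt, cc, 1)
        resid = cc - (slope * tt + intercept)
        ss_tot = np.sum((cc - cc.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if slope < 0 and (best is None or r2_adj > best[0] + 1e-12):
            best = (r2_adj, k, -slope)
    return best  # (r2_adj, n_points, lambda_z) or None


def nca(
    time: np.ndarray,
    conc: np.ndarray,
    lloq: float | None = None,
    extrapolate: bool = False,
) -> NCAResult:
    """Non-compartmental analysis of a sampled concentration profile.

    Values below ``lloq`` are treated as missing for the terminal fit
    (they still bound the trapezoid integration, which runs to the last
    quantifiable point).  Requires at least 3 time points.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 3:
        raise ValueError("need matched 1-D time/concentration arrays with >= 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if lloq is not None:
        keep = c >= lloq
        t, c = t[keep], c[keep]
        if len(t) < 3:
            raise ValueError("fewer than 3 quantifiable points above the LLOQ")

    cmax = float(c.max())
    tmax = float(t[int(np.argmax(c))])
    auc_last = float(np.trapezoid(c, t))
    aumc_last = float(np.trapezoid(c * t, t))
    mrt = aumc_last / auc_last if auc_last > 0 else float("nan")

    fit = _terminal_fit(t, c)
    if fit is None:
        return NCAResult(cmax, tmax, auc_last, aumc_last, mrt,
                         float("nan"), float("nan"), 0, float("nan"),
                         valid_terminal=False)
    r2_adj, n_pts, lam = fit
    result = NCAResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last, aumc_last=aumc_last,
        mrt=mrt, lambda_z=lam, t_half=float(np.log(2) / lam),
        n_terminal=n_pts, r2_adj_terminal=r2_adj,
    )
    if extrapolate:
        import dataclasses
        result = dataclasses.replace(
            result, extrapolated=True, auc_inf=auc_last + float(c[-1]) / lam)
    return result
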