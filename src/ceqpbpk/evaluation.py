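"""Goodness-of-fit metrics and parameter calibration against observed data.

Implements the three validation criteria conventional in veterinary
PBPK work — R^2 of observed vs predicted, mean absolute percentage
error (MAPE, acceptable below 50%), and the WHO twofold rule (fraction
of predictions within 0.5-2x of the observation) — plus bounded
nonlinear least-squares calibration of chemical parameters on
log-scale residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import simulate
from .parameters import ChemicalParams, DosingRegimen, PhysiologicalParams

OBSERVED_COLUMNS = ("study_id", "time_h", "compartment", "concentration", "lloq")


@dataclass
class ObservedDataset:
    """Observed concentration-time records for one study/regimen.

    ``data`` has columns time_h, compartment, concentration (ug/mL or
    ug/g) and optionally below_lloq; records flagged below the LLOQ are
    excluded from objectives and metrics.
    """

    data: pd.DataFrame
    regimen: DosingRegimen
    study_id: str = "study"
    lloq: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"time_h", "compartment", "concentration"} - set(self.data.columns)
        if missing:
            raise ValueError(f"observed data missing columns {sorted(missing)}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("observation times must be non-negative")
        quant = self.data["concentration"].dropna()
        if (quant < 0).any():
            raise ValueError("concentrations must be non-negative")

    def quantifiable(self) -> pd.DataFrame:
        d = self.data
        if "below_lloq" in d.columns:
            d = d[~d["below_lloq"].astype(bool)]
        return d[d["concentration"].notna() & (d["concentration"] >= self.lloq)]

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "study_id", self.study_id)
        out["lloq"] = self.lloq
        out.to_csv(path, index=False)


def r_squared(observed, predicted, via: str = "identity") -> float:
    """Coefficient of determination of predictions against observations.

    via="identity" (default) scores the predictions themselves:
    1 - SS(obs - pred) / SS(obs - mean(obs)), in (-inf, 1], with 0 for a
    flat predictor at the observed mean.  via="regression" returns the
    squared Pearson correlation of the fitted regression line, the
    quantity usually printed next to observed-vs-predicted scatter
    plots.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 3:
        raise ValueError("need paired arrays with at least 3 points")
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    if via == "identity":
        return float(1.0 - np.sum((o - p) ** 2) / ss_tot)
    if via == "regression":
        return float(np.corrcoef(o, p)[0, 1] ** 2)
    raise ValueError(f"unknown via={via!r}")


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, 100 * mean(|obs - pred| / obs)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size == 0:
        raise ValueError("need non-empty paired arrays")
    if np.any(o <= 0):
        raise ValueError("MAPE undefined for non-positive observations")
    return float(100.0 * np.mean(np.abs(o - p) / o))


def classify_mape(value: float) -> str:
    """Prediction-quality band: <10% excellent, <20% good, <50% acceptable."""
    if value < 10:
        return "excellent"
    if value < 20:
        return "good"
    if value < 50:
        return "acceptable"
    return "not acceptable"


def twofold_fraction(observed, predicted) -> float:
    """Fraction of predictions within twofold of the observation (0.5 <= pred/obs <= 2)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size == 0:
        raise ValueError("need non-empty paired arrays")
    if np.any(o <= 0):
        raise ValueError("twofold rule undefined for non-positive observations")
    ratio = p / o
    return float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))


@dataclass(frozen=True)
class FitSpec:
    """Which chemical parameters to free, their bounds, and the residual scale."""

    free_parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_residuals: bool = True

    def __post_init__(self) -> None:
        import dataclasses as dc
        known = {f.name for f in dc.fields(ChemicalParams)}
        for name in self.free_parameters:
            if name not in known:
                raise ValueError(f"{name!r} is not a chemical parameter")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite, positive, ordered")

    def bound_arrays(self, chem: ChemicalParams) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free_parameters:
            b = self.bounds.get(name)
            if b is None:
                v = getattr(chem, name)
                b = (v / 10.0, v * 10.0)  # generous default: one decade each way
            lo.append(b[0])
            hi.append(b[1])
        return np.asarray(lo), np.asarray(hi)


@dataclass
class FitReport:
    converged: bool
    objective: float
    message: str
    n_obs: int
    n_evaluations: int
    fitted_values: dict[str, float]
    dataset_metrics: pd.DataFrame


def _predict_dataset(
    ds: ObservedDataset,
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Model predictions matched to the quantifiable rows of a dataset."""
    q = ds.quantifiable()
    t_end = max(float(q["time_h"].max()), ds.regimen.last_dose_time) + dt
    series = simulate(phys, chem, ds.regimen, t_end, dt=dt)
    obs, pred = [], []
    for comp, grp in q.groupby("compartment"):
        trace = series.trace(comp)
        pred.append(np.interp(grp["time_h"].to_numpy(), series.time, trace))
        obs.append(grp["concentration"].to_numpy())
    return np.concatenate(obs), np.concatenate(pred)


def fit_parameters(
    datasets: list[ObservedDataset],
    spec: FitSpec,
    phys: PhysiologicalParams,
    chem_init: ChemicalParams,
    dt: float = 0.1,
) -> tuple[ChemicalParams, FitReport]:
    """Calibrate chemical parameters by bounded nonlinear least squares.

    Residuals are log(pred) - log(obs) by default, so datasets spanning
    orders of magnitude (residue depletion) weigh evenly with plasma
    profiles; every quantifiable observation has equal weight.  Returns
    the best-so-far parameters even on non-convergence (flagged in the
    report).
    """
    if not datasets:
        raise ValueError("need at least one observed dataset")
    if not spec.free_parameters:
        metrics = _metric_table(datasets, phys, chem_init, dt)
        report = FitReport(True, 0.0, "no free parameters", int(metrics["n"].sum()),
                           0, {}, metrics)
        return chem_init, report

    x0 = np.array([getattr(chem_init, p) for p in spec.free_parameters])
    lo, hi = spec.bound_arrays(chem_init)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial values must lie within bounds")

    floor = 1e-9  # concentration floor to keep log residuals finite

    def residuals(x: np.ndarray) -> np.ndarray:
        chem = chem_init.evolve(**dict(zip(spec.free_parameters, x)))
        res = []
        for ds in datasets:
            obs, pred = _predict_dataset(ds, phys, chem, dt)
            if spec.log_residuals:
                res.append(np.log(np.maximum(pred, floor)) - np.log(np.maximum(obs, floor)))
            else:
                res.append(pred - obs)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, bounds=(lo, hi), x_scale=np.maximum(x0, 1e-6),
                        xtol=1e-10, ftol=1e-10)
    fitted = chem_init.evolve(**dict(zip(spec.free_parameters, sol.x)))
    metrics = _metric_table(datasets, phys, fitted, dt)
    report = FitReport(
        converged=bool(sol.success),
        objective=float(2 * sol.cost),
        message=str(sol.message),
        n_obs=int(metrics["n"].sum()),
        n_evaluations=int(sol.nfev),
        fitted_values={p: float(v) for p, v in zip(spec.free_parameters, sol.x)},
        dataset_metrics=metrics,
    )
    return fitted, report


def _metric_table(datasets, phys, chem, dt) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        obs, pred = _predict_dataset(ds, phys, chem, dt)
        rows.append({
            "study_id": ds.study_id,
            "n": len(obs),
            "r_squared": r_squared(obs, pred) if len(obs) >= 3 else np.nan,
            "mape_pct": mape(obs, pred),
            "twofold_fraction": twofold_fraction(obs, pred),
        })
    return pd.DataFrame(rows)
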