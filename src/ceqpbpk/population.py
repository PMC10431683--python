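"""Monte Carlo population layer.

The influential parameters found by the sensitivity screen get
between-animal distributions: physiological parameters are normal,
chemical-specific parameters lognormal, each specified by a
natural-scale mean and CV and truncated to the central 95% (2.5th to
97.5th percentile) by rejection sampling.  Simulating 1000 virtual
pigs yields percentile bands for any compartment trace, the substrate
for %T>MIC target-attainment and withdrawal-interval estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import simulate
from .parameters import ChemicalParams, DosingRegimen, PhysiologicalParams


class SamplingError(RuntimeError):
    pass


def truncation_bounds(family: str, mean: float, cv: float) -> tuple[float, float]:
    """2.5th/97.5th percentiles of a normal or lognormal distribution.

    The lognormal is parameterised by its natural-scale mean and CV:
    sigma^2 = ln(1 + CV^2), mu = ln(mean) - sigma^2/2, so the
    distribution's arithmetic mean equals ``mean``.
    """
    if mean <= 0 or cv < 0:
        raise ValueError("mean must be positive and CV non-negative")
    if cv == 0:
        return mean, mean
    if family == "normal":
        sd = mean * cv
        return mean - 1.96 * sd, mean + 1.96 * sd
    if family == "lognormal":
        sigma2 = np.log1p(cv**2)
        sigma = np.sqrt(sigma2)
        mu = np.log(mean) - sigma2 / 2.0
        return float(np.exp(mu - 1.96 * sigma)), float(np.exp(mu + 1.96 * sigma))
    raise ValueError(f"unknown distribution family {family!r}")


@dataclass(frozen=True)
class ParameterDistribution:
    """Population distribution of one model parameter."""

    name: str
    family: str
    mean: float
    cv: float

    def __post_init__(self) -> None:
        truncation_bounds(self.family, self.mean, self.cv)  # validates

    @property
    def sd(self) -> float:
        return self.mean * self.cv

    @property
    def bounds(self) -> tuple[float, float]:
        return truncation_bounds(self.family, self.mean, self.cv)

    def sample(self, n: int, rng: np.random.Generator, max_rounds: int = 1000) -> np.ndarray:
        """Truncated draws by rejection (redraw outside the 95% bounds)."""
        if self.cv == 0:
            return np.full(n, self.mean)
        lo, hi = self.bounds
        out = np.empty(n)
        todo = np.arange(n)
        for _ in range(max_rounds):
            if self.family == "normal":
                draws = rng.normal(self.mean, self.sd, size=todo.size)
            else:
                sigma2 = np.log1p(self.cv**2)
                mu = np.log(self.mean) - sigma2 / 2.0
                draws = rng.lognormal(mu, np.sqrt(sigma2), size=todo.size)
            out[todo] = draws
            bad = (draws < lo) | (draws > hi)
            todo = todo[bad]
            if todo.size == 0:
                return out
        raise SamplingError(
            f"rejection sampling for {self.name} did not finish in {max_rounds} rounds")


# Population distributions of the influential parameters: physiological
# parameters normal with CV 0.30; partition coefficients and lung
# transfer rates lognormal with CV 0.20 and 0.30 respectively; renal
# clearance and lung tissue binding lognormal with CV 0.30.
DEFAULT_DISTRIBUTIONS: tuple[ParameterDistribution, ...] = (
    ParameterDistribution("QCC", "normal", 4.944, 0.30),
    ParameterDistribution("QKC", "normal", 0.1398, 0.30),
    ParameterDistribution("PL", "lognormal", 6.00, 0.20),
    ParameterDistribution("PK", "lognormal", 15.2, 0.20),
    ParameterDistribution("PM", "lognormal", 0.10, 0.20),
    ParameterDistribution("PR", "lognormal", 0.10, 0.20),
    ParameterDistribution("PLU", "lognormal", 1.50, 0.20),
    ParameterDistribution("KIT", "lognormal", 3.56, 0.30),
    ParameterDistribution("KTI", "lognormal", 2.60, 0.30),
    ParameterDistribution("KurineC", "lognormal", 0.30, 0.30),
    ParameterDistribution("PT", "lognormal", 0.30, 0.30),
)

_PHYS_FIELDS = {f.name for f in PhysiologicalParams.__dataclass_fields__.values()}


def sample_parameters(
    distributions: tuple[ParameterDistribution, ...],
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw n independent parameter sets (one row per virtual animal)."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pd.DataFrame({d.name: d.sample(n, rng) for d in distributions},
                        index=range(n))


def apply_overrides(
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    overrides: dict[str, float],
) -> tuple[PhysiologicalParams, ChemicalParams]:
    phys_kw = {k: v for k, v in overrides.items() if k in _PHYS_FIELDS}
    chem_kw = {k: v for k, v in overrides.items() if k not in _PHYS_FIELDS}
    return (phys.evolve(**phys_kw) if phys_kw else phys,
            chem.evolve(**chem_kw) if chem_kw else chem)


@dataclass
class PopulationEnsemble:
    """Traces of every virtual animal on a common grid.

    ``traces`` maps compartment name -> array of shape (n_individuals,
    n_times).  ``parameters`` holds the sampled parameter sets,
    ``n_resampled`` counts individuals whose first draw failed to
    integrate and was redrawn.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    parameters: pd.DataFrame
    regimen: DosingRegimen
    seed: int | None
    n_resampled: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.parameters)

    def percentiles(self, compartment: str, probs) -> np.ndarray:
        return percentiles(self, compartment, probs)


def simulate_population(
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    regimen: DosingRegimen,
    t_end: float,
    distributions: tuple[ParameterDistribution, ...] = DEFAULT_DISTRIBUTIONS,
    n: int = 1000,
    seed: int | None = 0,
    compartments: tuple[str, ...] = ("plasma", "plasma_free", "arterial_free", "lung_if", "lung_pelf"),
    dt: float = 0.05,
    plu_variant: str = "tissue_partition",
    max_resample: int = 100,
) -> PopulationEnsemble:
    """Simulate n virtual animals with parameters drawn per individual.

    Reproducible for a given seed.  On the rare integration failure the
    individual's parameters are redrawn (counted in ``n_resampled``).
    """
    rng = np.random.default_rng(seed)
    params = sample_parameters(distributions, n, rng)
    traces: dict[str, np.ndarray] | None = None
    n_resampled = 0
    for i in range(n):
        for attempt in range(max_resample + 1):
            try:
                ph, ch = apply_overrides(phys, chem, params.iloc[i].to_dict())
                s = simulate(ph, ch, regimen, t_end, dt=dt, plu_variant=plu_variant)
                break
            except Exception:
                if attempt >= max_resample:
                    raise
                redraw = sample_parameters(distributions, 1, rng)
                params.iloc[i] = redraw.iloc[0]
                n_resampled += 1
        if traces is None:
            traces = {c: np.empty((n, s.time.size)) for c in compartments}
            time = s.time
        for c in compartments:
            traces[c][i] = s.trace(c)
    return PopulationEnsemble(
        time=time, traces=traces, parameters=params, regimen=regimen,
        seed=seed if isinstance(seed, int) else None, n_resampled=n_resampled,
        meta={"phys": phys, "chem": chem, "dt": dt, "plu_variant": plu_variant},
    )


def percentiles(ensemble: PopulationEnsemble, compartment: str, probs) -> np.ndarray:
    """Pointwise empirical percentiles (linear-interpolation order statistic).

    Returns an array of shape (len(probs), n_times).
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 100)):
        raise ValueError("percentile probs must lie strictly between 0 and 100")
    try:
        arr = ensemble.traces[compartment]
    except KeyError:
        raise KeyError(f"compartment {compartment!r} not stored in ensemble") from None
    if arr.shape[0] == 0:
        raise ValueError("empty ensemble")
    return np.percentile(arr, probs, axis=0)


def summary_frame(ensemble: PopulationEnsemble, probs=(1, 10, 50, 90, 99)) -> pd.DataFrame:
    """Long-format percentile summary: time_h, compartment, p01..p99."""
    rows = []
    for comp in ensemble.traces:
        pct = percentiles(ensemble, comp, probs)
        df = pd.DataFrame({"time_h": ensemble.time, "compartment": comp})
        for p, tr in zip(probs, pct):
            df[f"p{int(p):02d}"] = tr
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
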