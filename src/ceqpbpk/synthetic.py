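"""Synthetic observed-data generator.

Emulates the study designs the calibration pipeline expects — a
single-IM-dose plasma profile, five-day liver/kidney residue-depletion
sampling, and a microdialysis dialysate profile — by simulating the
PBPK model per animal (with between-animal parameter variation drawn
from the population distributions), evaluating at the design's
sampling times, applying multiplicative lognormal assay noise, and
censoring below the LLOQ.  The generating truth is recorded in the
dataset metadata so parameter-recovery tests can close the loop.

The noise model emulates chromatographic assay error plus residual
biological variation; it does not model assay drift, carryover or
probe degradation, so recovery results bound what the pipeline can do
on clean data, not on pathological assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ObservedDataset
from .model import simulate
from .parameters import ChemicalParams, DosingRegimen, PhysiologicalParams
from .population import ParameterDistribution, apply_overrides, sample_parameters

#: dialysate sampling schedule of the microdialysis experiment, h
DIALYSATE_TIMES = (0.25, 0.5, 0.75, 1.0, 1.25, 1.75, 2.25, 3.25,
                   4.25, 5.25, 7.25, 9.25, 10.25, 11.25)

#: plasma sampling after a single IM dose, h
PLASMA_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)

#: residue sampling days after the last of 5 daily doses, h post first dose
RESIDUE_TIMES = tuple(96.0 + 24.0 * d for d in range(1, 6))


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal residual error with LLOQ handling.

    ``cv`` is the assay coefficient of variation; draws have unit mean.
    Below-LLOQ values are censored (kept as missing, flagged) or
    dropped.
    """

    cv: float = 0.20
    lloq: float = 0.05
    below_lloq: str = "censor"

    def __post_init__(self) -> None:
        if self.cv < 0 or self.lloq < 0:
            raise ValueError("cv and lloq must be non-negative")
        if self.below_lloq not in ("censor", "drop"):
            raise ValueError("below_lloq must be 'censor' or 'drop'")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float)
        sigma2 = np.log1p(self.cv**2)
        factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=np.shape(values))
        return np.asarray(values, dtype=float) * factors


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: who is dosed how, and what is measured when."""

    regimen: DosingRegimen
    compartments: tuple[str, ...]
    times: tuple[float, ...]
    n_animals: int = 1
    distributions: tuple[ParameterDistribution, ...] = ()
    study_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if list(self.times) != sorted(self.times):
            raise ValueError("sampling times must be sorted")


def single_dose_plasma_design(n_animals: int = 5, dose: float = 2.0,
                              distributions=()) -> StudyDesign:
    return StudyDesign(DosingRegimen(dose), ("plasma",), PLASMA_TIMES,
                       n_animals, tuple(distributions), "plasma_single_im")


def residue_depletion_design(n_animals: int = 8, dose: float = 2.0,
                             distributions=()) -> StudyDesign:
    return StudyDesign(DosingRegimen(dose, interval_h=24.0, n_doses=5),
                       ("liver", "kidney"), RESIDUE_TIMES,
                       n_animals, tuple(distributions), "residue_depletion")


def _simulate_animal(design, phys, chem, overrides, dt):
    ph, ch = apply_overrides(phys, chem, overrides)
    t_end = max(max(design.times), design.regimen.last_dose_time) + dt
    return simulate(ph, ch, design.regimen, t_end, dt=dt)


def generate_study(
    design: StudyDesign,
    noise: NoiseModel,
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    seed: int = 0,
    dt: float = 0.05,
) -> ObservedDataset:
    """Simulate the design and emit noisy, LLOQ-handled observations."""
    rng = np.random.default_rng(seed)
    overrides = (sample_parameters(design.distributions, design.n_animals, rng)
                 if design.distributions else pd.DataFrame(index=range(design.n_animals)))
    rows = []
    for i in range(design.n_animals):
        series = _simulate_animal(design, phys, chem, overrides.iloc[i].to_dict(), dt)
        for comp in design.compartments:
            truth = np.interp(design.times, series.time, series.trace(comp))
            observed = noise.apply(truth, rng)
            for t, v in zip(design.times, observed):
                rows.append({"animal": i, "time_h": t, "compartment": comp,
                             "concentration": v})
    data = pd.DataFrame(rows)
    below = data["concentration"] < noise.lloq
    if noise.below_lloq == "drop":
        data = data[~below].reset_index(drop=True)
        data["below_lloq"] = False
    else:
        data["below_lloq"] = below
        data.loc[below, "concentration"] = np.nan
    return ObservedDataset(
        data=data, regimen=design.regimen, study_id=design.study_id,
        lloq=noise.lloq,
        meta={"truth": {"phys": phys, "chem": chem,
                        "overrides": overrides.to_dict("records")},
              "noise": noise, "seed": seed},
    )


def generate_dialysate_study(
    design: StudyDesign,
    in_vivo_rr: float,
    noise: NoiseModel,
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    seed: int = 0,
    dt: float = 0.05,
) -> ObservedDataset:
    """Dialysate observations: RR x simulated lung-IF concentration x noise.

    Round-trips with :func:`ceqpbpk.nca.correct_isf`, which divides the
    dialysate trace by the in vivo relative recovery.
    """
    if not 0.0 < in_vivo_rr <= 1.0:
        raise ValueError("in vivo RR must be a fraction in (0, 1]")
    rng = np.random.default_rng(seed)
    overrides = (sample_parameters(design.distributions, design.n_animals, rng)
                 if design.distributions else pd.DataFrame(index=range(design.n_animals)))
    rows = []
    for i in range(design.n_animals):
        series = _simulate_animal(design, phys, chem, overrides.iloc[i].to_dict(), dt)
        isf = np.interp(design.times, series.time, series.trace("lung_if"))
        observed = noise.apply(in_vivo_rr * isf, rng)
        for t, v in zip(design.times, observed):
            rows.append({"animal": i, "time_h": t, "compartment": "dialysate",
                         "concentration": v})
    data = pd.DataFrame(rows)
    below = data["concentration"] < noise.lloq
    if noise.below_lloq == "drop":
        data = data[~below].reset_index(drop=True)
        data["below_lloq"] = False
    else:
        data["below_lloq"] = below
        data.loc[below, "concentration"] = np.nan
    return ObservedDataset(
        data=data, regimen=design.regimen, study_id=design.study_id, lloq=noise.lloq,
        meta={"truth": {"phys": phys, "chem": chem, "in_vivo_rr": in_vivo_rr,
                        "overrides": overrides.to_dict("records")},
              "noise": noise, "seed": seed},
    )
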