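"""Local sensitivity analysis: normalized sensitivity coefficients (NSC).

Each scalar model parameter p is increased by a fraction (10% by
default) and the 24-h AUC r of a compartment concentration is
re-simulated; NSC = (dr/r) / (dp/p).  |NSC| > 0.25 marks a parameter
as influential; the influential set drives which parameters get
population distributions in the Monte Carlo layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import auc, simulate
from .parameters import ChemicalParams, DosingRegimen, PhysiologicalParams

INFLUENTIAL_THRESHOLD = 0.25

# All perturbable scalar inputs. The balancing remainders (QRC, VRC,
# VLUT) are derived quantities and are held out of the roster;
# perturbing a sibling fraction deliberately leaves the sums
# unbalanced, as is standard for one-at-a-time local sensitivity.
# QLUC is excluded too: the lung carries the whole cardiac output by
# construction, so QLUC is structurally fixed at 1.
PHYS_PARAMETERS = (
    "BW", "QCC", "QMC", "QLC", "QKC",
    "VLUC", "VMC", "VLC", "VKC", "VartC", "VvenC", "VLUB", "VLUI",
)
CHEM_PARAMETERS = (
    "PLU", "PM", "PR", "PL", "PK",
    "Kim", "Frac", "Kdiss", "KbileC", "KurineC",
    "PB", "PT", "KBI", "KIB", "KIT", "KTI",
)
ALL_PARAMETERS = PHYS_PARAMETERS + CHEM_PARAMETERS

DEFAULT_COMPARTMENTS = ("plasma", "liver", "kidney", "muscle", "rest", "lung", "lung_if")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    compartment: str
    baseline_auc: float
    delta_frac: float
    nsc: float

    @property
    def influential(self) -> bool:
        return abs(self.nsc) > INFLUENTIAL_THRESHOLD


# When a fraction with a "calculated" sibling remainder is perturbed,
# the remainder re-balances so the budget it closes stays constant
# (QRC absorbs flow-fraction changes, VRC organ-volume changes, VLUT
# lung sub-volume changes) — mirroring how those remainders are
# defined in the parameter table.
_REBALANCE = {
    "QMC": "QRC", "QLC": "QRC", "QKC": "QRC",
    "VLUC": "VRC", "VMC": "VRC", "VLC": "VRC", "VKC": "VRC",
    "VartC": "VRC", "VvenC": "VRC",
    "VLUB": "VLUT", "VLUI": "VLUT",
}


def _perturb(phys: PhysiologicalParams, chem: ChemicalParams, name: str, factor: float):
    if name in PHYS_PARAMETERS:
        old = getattr(phys, name)
        changes = {name: old * factor}
        remainder = _REBALANCE.get(name)
        if remainder is not None:
            new_rem = getattr(phys, remainder) - old * (factor - 1.0)
            if new_rem <= 0:
                raise ValueError(
                    f"perturbing {name} by {factor:g} exhausts the {remainder} remainder")
            changes[remainder] = new_rem
        return phys.evolve(**changes), chem
    if name in CHEM_PARAMETERS:
        return phys, chem.evolve(**{name: getattr(chem, name) * factor})
    raise ValueError(f"unknown or non-perturbable parameter {name!r}")


def nsc(
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    regimen: DosingRegimen,
    parameter: str,
    compartment: str,
    t_horizon: float = 24.0,
    delta_frac: float = 0.10,
    difference: str = "forward",
    plu_variant: str = "tissue_partition",
    _baseline: float | None = None,
) -> SensitivityResult:
    """Normalized sensitivity coefficient of one parameter on one AUC.

    difference="forward" simulates at p and (1+delta)*p, matching the
    usual increase-by-10% protocol; "central" uses (1±delta/2)*p.
    """
    if delta_frac <= 0:
        raise ValueError("delta_frac must be positive")
    if difference not in ("forward", "central"):
        raise ValueError(f"unknown difference scheme {difference!r}")

    def run(ph, ch):
        s = simulate(ph, ch, regimen, t_horizon, plu_variant=plu_variant)
        return auc(s, compartment, 0.0, t_horizon)

    if difference == "forward":
        r0 = run(phys, chem) if _baseline is None else _baseline
        r1 = run(*_perturb(phys, chem, parameter, 1.0 + delta_frac))
        if r0 == 0:
            raise ValueError(f"baseline AUC of {compartment!r} is zero; NSC undefined")
        value = (r1 - r0) / r0 / delta_frac
        base = r0
    else:
        r_lo = run(*_perturb(phys, chem, parameter, 1.0 - delta_frac / 2))
        r_hi = run(*_perturb(phys, chem, parameter, 1.0 + delta_frac / 2))
        base = run(phys, chem) if _baseline is None else _baseline
        if base == 0:
            raise ValueError(f"baseline AUC of {compartment!r} is zero; NSC undefined")
        value = (r_hi - r_lo) / base / delta_frac
    return SensitivityResult(parameter, compartment, float(base), delta_frac, float(value))


def sensitivity_screen(
    phys: PhysiologicalParams,
    chem: ChemicalParams,
    regimen: DosingRegimen,
    parameters: tuple[str, ...] = ALL_PARAMETERS,
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS,
    t_horizon: float = 24.0,
    delta_frac: float = 0.10,
    plu_variant: str = "tissue_partition",
) -> pd.DataFrame:
    """Full NSC matrix over parameters x compartments.

    One simulation per perturbed parameter; baseline AUCs are shared
    across compartments.  Returns a long table with columns parameter,
    compartment, baseline_auc, nsc, influential.
    """
    if delta_frac <= 0:
        raise ValueError("delta_frac must be positive")
    base_series = simulate(phys, chem, regimen, t_horizon, plu_variant=plu_variant)
    base = {c: auc(base_series, c, 0.0, t_horizon) for c in compartments}
    rows = []
    for p in parameters:
        ph, ch = _perturb(phys, chem, p, 1.0 + delta_frac)
        pert_series = simulate(ph, ch, regimen, t_horizon, plu_variant=plu_variant)
        for c in compartments:
            r0 = base[c]
            r1 = auc(pert_series, c, 0.0, t_horizon)
            value = np.nan if r0 == 0 else (r1 - r0) / r0 / delta_frac
            rows.append({
                "parameter": p, "compartment": c, "baseline_auc": r0,
                "nsc": value,
                "influential": bool(abs(value) > INFLUENTIAL_THRESHOLD) if np.isfinite(value) else False,
            })
    return pd.DataFrame(rows)


def influential_parameters(screen: pd.DataFrame) -> list[str]:
    """Parameters influential (|NSC| > 0.25) for at least one compartment."""
    flagged = screen[screen["influential"]]
    return sorted(flagged["parameter"].unique())
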