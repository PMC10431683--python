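"""Model parameters for the swine cefquinome PBPK model.

The model describes a ~25 kg nursery pig receiving cefquinome by
intramuscular injection.  Physiology is parameterised by cardiac output,
fractional organ blood flows and fractional organ volumes; the drug by
tissue:blood partition coefficients, a two-rate intramuscular depot,
hepatic/renal clearances, protein binding and the first-order transfer
rates of the permeability-limited lung sub-model.

Units convention used throughout the package: amounts mg, volumes L,
time h, flows L/h, concentrations mg/L (= ug/mL = ug/g at tissue
density 1 g/mL).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


class InvalidParameterError(ValueError):
    """A parameter value violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class PhysiologicalParams:
    """Swine physiological parameters.

    Fractional blood flows (``Q*C``) are fractions of cardiac output;
    fractional volumes (``V*C``) are fractions of body weight.  The lung
    receives the whole cardiac output (``QLUC = 1``) because it sits in
    series between the venous and arterial pools.  ``QRC`` and ``VRC``
    ("rest of body") are balancing remainders, so the flow and volume
    fractions sum to ~1 rather than exactly 1.

    Attributes
    ----------
    BW : body weight, kg.
    QCC : cardiac output, L/h/kg.
    QMC, QRC, QLC, QKC : fractional blood flow to muscle, rest of body,
        liver and kidney (of cardiac output).
    QLUC : fraction of cardiac output through the lung (1.0).
    VLUC, VMC, VRC, VLC, VKC : fractional volumes of lung, muscle, rest,
        liver and kidney (of body weight).
    VartC, VvenC : arterial and venous blood fractional volumes.
    VLUB, VLUI, VLUT : lung blood / interstitial fluid / tissue volumes
        as fractions of the whole lung.
    """

    BW: float = 25.0
    QCC: float = 4.944
    QMC: float = 0.2524
    QRC: float = 0.3055
    QLC: float = 0.3053
    QKC: float = 0.1398
    QLUC: float = 1.0
    VLUC: float = 0.01
    VMC: float = 0.4
    VRC: float = 0.232
    VLC: float = 0.0294
    VKC: float = 0.004
    VartC: float = 0.016
    VvenC: float = 0.044
    VLUB: float = 0.262
    VLUI: float = 0.188
    VLUT: float = 0.55

    def __post_init__(self) -> None:
        _require(self.BW > 0, f"body weight must be positive, got {self.BW}")
        _require(self.QCC > 0, f"cardiac output must be positive, got {self.QCC}")
        for name in ("QMC", "QRC", "QLC", "QKC", "QLUC", "VLUC", "VMC", "VRC",
                     "VLC", "VKC", "VartC", "VvenC", "VLUB", "VLUI", "VLUT"):
            v = getattr(self, name)
            _require(v > 0, f"{name} must be positive, got {v}")
            _require(v <= 1.0 + 1e-12, f"{name} is a fraction and must be <= 1, got {v}")

    def check_balance(self, tol_low: float = 0.99, tol_high: float = 1.01) -> None:
        """Verify that flow and lung sub-volume fractions sum to ~1.

        Called when parameters are loaded from a config file or taken as
        study defaults.  Deliberately *not* called on every construction:
        single-parameter perturbations (sensitivity analysis, Monte Carlo
        sampling of QKC) intentionally unbalance the sums, mirroring how
        local sensitivity is normally computed for PBPK models.
        """
        qsum = self.QMC + self.QRC + self.QLC + self.QKC
        _require(tol_low <= qsum <= tol_high,
                 f"fractional blood flows sum to {qsum:.4f}, outside [{tol_low}, {tol_high}]")
        vsum = self.VLUB + self.VLUI + self.VLUT
        _require(tol_low <= vsum <= tol_high,
                 f"lung sub-volume fractions sum to {vsum:.4f}, outside [{tol_low}, {tol_high}]")

    def evolve(self, **changes: float) -> "PhysiologicalParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ChemicalParams:
    """Cefquinome-specific parameters.

    Attributes
    ----------
    PLU, PM, PR, PL, PK : tissue:blood partition coefficients for lung,
        muscle, rest of body, liver and kidney (unitless).
    Kim : first-order absorption rate of the fast depot pool into venous
        blood, /h.
    Frac : fraction of each intramuscular dose deposited in the *slow*
        depot pool (the remainder is immediately available for fast
        absorption).
    Kdiss : first-order release rate of the slow pool into the fast
        pool, /h.
    KbileC, KurineC : hepatic and renal clearance, L/h/kg body weight.
    PB : plasma protein-bound fraction (unitless).
    PT : lung-tissue protein-bound fraction (unitless).
    KBI, KIB : lung blood <-> interstitial fluid transfer rates, /h.
    KIT, KTI : interstitial fluid <-> lung tissue transfer rates, /h.
    """

    PLU: float = 1.5
    PM: float = 0.1
    PR: float = 0.1
    PL: float = 6.0
    PK: float = 15.2
    Kim: float = 7.0
    Frac: float = 0.1
    Kdiss: float = 0.05
    KbileC: float = 0.01
    KurineC: float = 0.3
    PB: float = 0.188
    PT: float = 0.3
    KBI: float = 0.110
    KIB: float = 0.052
    KIT: float = 3.56
    KTI: float = 2.60

    def __post_init__(self) -> None:
        for name in ("PLU", "PM", "PR", "PL", "PK", "Kim", "Kdiss",
                     "KbileC", "KurineC", "KBI", "KIB", "KIT", "KTI"):
            v = getattr(self, name)
            _require(v >= 0, f"{name} must be non-negative, got {v}")
        for name in ("Frac", "PB", "PT"):
            v = getattr(self, name)
            _require(0 <= v <= 1, f"{name} is a fraction in [0, 1], got {v}")
        for name in ("PLU", "PM", "PR", "PL", "PK"):
            _require(getattr(self, name) > 0,
                     f"partition coefficient {name} must be positive")

    def evolve(self, **changes: float) -> "ChemicalParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DosingRegimen:
    """An intramuscular multiple-dose schedule.

    Parameters
    ----------
    dose_per_kg : dose level, mg/kg body weight.
    interval_h : hours between consecutive doses.
    n_doses : number of doses.
    start_h : time of the first dose, h.
    """

    dose_per_kg: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_h: float = 0.0
    route: str = "im"

    def __post_init__(self) -> None:
        _require(self.dose_per_kg >= 0, "dose must be non-negative")
        _require(self.n_doses >= 1, "need at least one dose")
        if self.n_doses > 1:
            _require(self.interval_h > 0, "interval must be positive for multiple doses")
        _require(self.start_h >= 0, "first dose time must be non-negative")
        _require(self.route == "im", f"only intramuscular dosing is modelled, got {self.route!r}")

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(self.start_h + i * self.interval_h for i in range(self.n_doses))

    @property
    def last_dose_time(self) -> float:
        return self.dose_times[-1]

    def dose_mg(self, bw_kg: float) -> float:
        """Amount per administration, mg."""
        return self.dose_per_kg * bw_kg

    def total_dose_mg(self, bw_kg: float) -> float:
        return self.n_doses * self.dose_mg(bw_kg)


@dataclass(frozen=True)
class DerivedQuantities:
    """Absolute flows (L/h) and volumes (L) derived from fractional parameters."""

    QC: float   # cardiac output, L/h
    QM: float
    QR: float
    QL: float
    QK: float
    V_lung: float
    V_muscle: float
    V_rest: float
    V_liver: float
    V_kidney: float
    V_art: float
    V_ven: float
    V_lung_blood: float
    V_lung_if: float
    V_lung_tissue: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def derived_quantities(phys: PhysiologicalParams) -> DerivedQuantities:
    """Scale fractional flows and volumes to absolute L/h and L.

    Organ flows are fractions of cardiac output ``QC = QCC * BW``; organ
    volumes are fractions of body weight at density 1 kg/L; the lung
    sub-compartment volumes are fractions of the whole-lung volume.
    """
    _require(phys.BW > 0, "body weight must be positive")
    qc = phys.QCC * phys.BW
    v_lung = phys.VLUC * phys.BW
    return DerivedQuantities(
        QC=qc,
        QM=phys.QMC * qc,
        QR=phys.QRC * qc,
        QL=phys.QLC * qc,
        QK=phys.QKC * qc,
        V_lung=v_lung,
        V_muscle=phys.VMC * phys.BW,
        V_rest=phys.VRC * phys.BW,
        V_liver=phys.VLC * phys.BW,
        V_kidney=phys.VKC * phys.BW,
        V_art=phys.VartC * phys.BW,
        V_ven=phys.VvenC * phys.BW,
        V_lung_blood=phys.VLUB * v_lung,
        V_lung_if=phys.VLUI * v_lung,
        V_lung_tissue=phys.VLUT * v_lung,
    )


def load_params(path: str | Path) -> tuple[PhysiologicalParams, ChemicalParams]:
    """Read parameters from a TOML file with [physiology] and [chemical] tables.

    Either table may be partial or absent; missing keys fall back to the
    package defaults.  Flow/volume balance is checked on load.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    phys_kw = raw.get("physiology", {})
    chem_kw = raw.get("chemical", {})
    known_phys = {f.name for f in dataclasses.fields(PhysiologicalParams)}
    known_chem = {f.name for f in dataclasses.fields(ChemicalParams)}
    for k in phys_kw:
        _require(k in known_phys, f"unknown physiological parameter {k!r}")
    for k in chem_kw:
        _require(k in known_chem, f"unknown chemical parameter {k!r}")
    phys = PhysiologicalParams(**phys_kw)
    phys.check_balance()
    return phys, ChemicalParams(**chem_kw)


def default_params() -> tuple[PhysiologicalParams, ChemicalParams]:
    """The study defaults for a 25 kg pig (balance-checked)."""
    phys = PhysiologicalParams()
    phys.check_balance()
    return phys, ChemicalParams()
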