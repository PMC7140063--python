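"""Chemotherapy regimens and human-to-fish dose arithmetic.

A *regimen* is an ordered combination of drugs with their human clinical
doses (mg per m^2 of body surface area).  For a reference patient with body
surface area ``bsa`` (m^2) and blood volume ``V`` (mL), the total
administered mass of a drug is ``M = clinical_dose * bsa`` (mg) and its
*equivalent plasma concentration* is

    EPC = M / V          (mg/mL),

the human-side anchor of the dose conversion.  Dissolving the regimen in
fish water at the mass ratios used in humans and dividing every EPC by a
dimensionless dilution factor (the *equivalent dose*, ED) gives the
fish-water concentration of each component:

    c_fish = (M / V) / ED        (mg/mL).

All values are stored at full precision; :func:`display_round` implements
the 2-decimal display rule used in summary tables and
:func:`format_mass_ratio` the ratio strings (3 significant figures).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .exceptions import DomainError, InputError

__all__ = [
    "Drug",
    "Regimen",
    "PatientReference",
    "EPCProfile",
    "compute_epc",
    "mass_ratios",
    "fish_water_concentrations",
    "format_mass_ratio",
    "display_round",
    "load_regimens",
    "builtin_regimens",
]


@dataclass(frozen=True)
class Drug:
    """One component drug with its human clinical dose (mg/m^2)."""

    name: str
    clinical_dose: float

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("drug name must be non-empty")
        if not self.clinical_dose > 0:
            raise DomainError(
                f"clinical dose must be > 0, got {self.clinical_dose!r} for {self.name}"
            )


@dataclass(frozen=True)
class Regimen:
    """An ordered drug combination; ``index_drug`` labels safety assays.

    The index drug is the component whose fish-water concentration is
    reported on the x-axis of the safety dose-response experiments
    (gemcitabine for the GEM family, 5-fluorouracil for the 5-FU family).
    """

    name: str
    drugs: tuple[Drug, ...]
    index_drug: str | None = None

    def __post_init__(self) -> None:
        if not self.drugs:
            raise InputError(f"regimen {self.name!r} has no drugs")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate drug names in regimen {self.name!r}")
        object.__setattr__(self, "drugs", tuple(self.drugs))
        if self.index_drug is None:
            object.__setattr__(self, "index_drug", self.drugs[0].name)
        elif self.index_drug not in names:
            raise InputError(
                f"index drug {self.index_drug!r} not a member of regimen {self.name!r}"
            )

    @property
    def drug_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drugs)

    def drug(self, name: str) -> Drug:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def index(self) -> Drug:
        return self.drug(self.index_drug)


@dataclass(frozen=True)
class PatientReference:
    """Reference human used for the conversion: BSA (m^2), blood volume (mL)."""

    bsa: float = 1.8
    blood_volume: float = 5400.0

    def __post_init__(self) -> None:
        if not self.bsa > 0 or not self.blood_volume > 0:
            raise DomainError("BSA and blood volume must be strictly positive")


@dataclass(frozen=True)
class EPCProfile:
    """Per-drug equivalent plasma concentrations of one regimen.

    ``epc[name] = mass[name] / blood_volume`` for every drug, with ``mass``
    the total administered amount M (mg).
    """

    regimen: str
    epc: Mapping[str, float]
    mass: Mapping[str, float]
    blood_volume: float

    def __post_init__(self) -> None:
        for name, value in self.epc.items():
            if not value > 0:
                raise DomainError(f"EPC of {name!r} must be > 0")
            expected = self.mass[name] / self.blood_volume
            if abs(value - expected) > 1e-12 * max(1.0, expected):
                raise InputError(f"EPC of {name!r} inconsistent with M/V")


def compute_epc(drug: Drug, ref: PatientReference = PatientReference()) -> float:
    """EPC (mg/mL) of one drug: clinical_dose x BSA / blood volume.

    Full precision is retained; round only for display via
    :func:`display_round`.
    """
    return drug.clinical_dose * ref.bsa / ref.blood_volume


def epc_profile(regimen: Regimen, ref: PatientReference = PatientReference()) -> EPCProfile:
    """EPC of every component drug of a regimen."""
    mass = {d.name: d.clinical_dose * ref.bsa for d in regimen.drugs}
    epc = {name: m / ref.blood_volume for name, m in mass.items()}
    return EPCProfile(regimen=regimen.name, epc=epc, mass=mass, blood_volume=ref.blood_volume)


def mass_ratios(regimen: Regimen) -> tuple[float, ...]:
    """Dimensionless drug-mass ratios, normalised to the minimum dose.

    Each clinical dose is divided by the smallest dose of the combination,
    so the lowest-dose component has ratio exactly 1.  Ratios are invariant
    under rescaling all doses (and under the BSA factor), hence they are
    mass ratios as well as dose ratios.
    """
    doses = [d.clinical_dose for d in regimen.drugs]
    lowest = min(doses)
    return tuple(dose / lowest for dose in doses)


def fish_water_concentrations(profile: EPCProfile, ed: float) -> dict[str, float]:
    """Fish-water concentration (mg/mL) per drug: EPC / ED.

    ``ed`` is the dimensionless equivalent dose (dilution factor).  Mass
    ratios among component drugs are preserved exactly.
    """
    if not ed > 0:
        raise DomainError(f"equivalent dose must be > 0, got {ed!r}")
    return {name: value / ed for name, value in profile.epc.items()}


def display_round(value: float, decimals: int = 2) -> float:
    """Display rule for concentrations: round half away from zero."""
    import math

    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def format_mass_ratio(ratios: Iterable[float]) -> str:
    """Format a ratio tuple like ``37.6:2.35:1.94:1`` (3 significant figures)."""
    parts = []
    for r in ratios:
        if r == int(r):
            parts.append(str(int(r)))
        else:
            parts.append(f"{r:.3g}")
    return ":".join(parts)


def _parse_regimen(entry: Mapping) -> Regimen:
    try:
        drugs = tuple(
            Drug(name=d["name"], clinical_dose=float(d["clinical_dose_mg_per_m2"]))
            for d in entry["drugs"]
        )
        return Regimen(name=entry["name"], drugs=drugs, index_drug=entry.get("index_drug"))
    except (KeyError, TypeError) as exc:
        raise InputError(f"malformed regimen entry {entry!r}: {exc}") from exc


def load_regimens(path: str | Path) -> dict[str, Regimen]:
    """Read a regimen YAML file into a name -> :class:`Regimen` mapping."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "regimens" not in doc:
        raise InputError(f"{path}: expected a mapping with a 'regimens' list")
    regimens = {}
    for entry in doc["regimens"]:
        reg = _parse_regimen(entry)
        if reg.name in regimens:
            raise InputError(f"duplicate regimen name {reg.name!r}")
        regimens[reg.name] = reg
    return regimens


def builtin_regimens() -> dict[str, Regimen]:
    """The packaged regimen table of the ten studied protocols."""
    source = importlib.resources.files("fishdose.data") / "regimens.yaml"
    with importlib.resources.as_file(source) as path:
        return load_regimens(path)
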