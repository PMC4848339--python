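"""Greenness scoring of analytical procedures: NEMI profiles, Eco-Scale,
and hazard-weighted solvent totals.

NEMI assigns a four-field pictogram: a field is green when the procedure
(1) uses no chemical on the persistence/bioaccumulation/toxicity (PBT)
lists, (2) uses no chemical on the K/F/P/U hazardous-waste lists, (3) keeps
the sample pH within 2-12, and (4) produces less than 50 g of waste.  The
score is the number of green fields, 0-4.

The Eco-Scale starts at 100 and subtracts penalty points for reagents,
energy, occupational hazard and waste.  Penalty points are first-class
inputs here; a default penalty table (from the cited Eco-Scale reference,
not re-derived) ships as an editable JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import ValidationError

PICTOGRAMS = ("none", "warning", "danger")
#: Hazard multiplier applied to a solvent amount per its GHS signal word.
HAZARD_MULTIPLIER = {"none": 0.0, "warning": 1.0, "danger": 2.0}

#: NEMI waste criterion: strictly less than 50 g of waste.
NEMI_WASTE_LIMIT_G = 50.0
#: NEMI corrosivity criterion: sample pH within [2, 12] (closed interval).
NEMI_PH_RANGE = (2.0, 12.0)


@dataclass(frozen=True)
class ChemicalUsage:
    """One chemical used by a procedure.

    ``amount`` is in mL for solvents and g for solids (``unit``).  List
    membership flags are supplied by the caller — regulatory lists change,
    so none is hard-coded.
    """

    name: str
    amount: float
    pictogram: str = "none"
    on_pbt_list: bool = False
    on_kfpu_list: bool = False
    unit: str = "mL"

    def __post_init__(self):
        if self.amount < 0:
            raise ValidationError(f"{self.name}: negative amount {self.amount}")
        if self.pictogram not in PICTOGRAMS:
            raise ValidationError(
                f"{self.name}: pictogram must be one of {PICTOGRAMS}, "
                f"got {self.pictogram!r}"
            )


@dataclass
class ProcedureInventory:
    """Everything needed to score one procedure: chemicals with amounts and
    hazard flags, the sample pH, the waste mass, and Eco-Scale penalty
    points as (label, points) pairs."""

    chemicals: list[ChemicalUsage] = field(default_factory=list)
    sample_ph: float = 7.0
    waste_mass: float = 0.0
    penalty_points: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.waste_mass < 0:
            raise ValidationError(f"negative waste mass {self.waste_mass}")
        for label, pts in self.penalty_points:
            if pts < 0:
                raise ValidationError(f"negative penalty {pts} for {label!r}")


@dataclass(frozen=True)
class NemiProfile:
    """The four NEMI pictogram fields, True = green."""

    pbt_ok: bool
    hazard_ok: bool
    corrosive_ok: bool
    waste_ok: bool

    @property
    def green_count(self) -> int:
        return int(self.pbt_ok) + int(self.hazard_ok) \
            + int(self.corrosive_ok) + int(self.waste_ok)


def hazard_weighted_amount(chemicals: Iterable[ChemicalUsage]) -> float:
    """Total solvent amount weighted by hazard.

    Each amount (mL) is multiplied by 0 / 1 / 2 for no pictogram / warning /
    danger, and the products are summed.
    """
    total = 0.0
    for chem in chemicals:
        if chem.unit != "mL":
            raise ValidationError(
                f"{chem.name}: hazard weighting applies to solvent volumes "
                f"(mL), got unit {chem.unit!r}"
            )
        total += chem.amount * HAZARD_MULTIPLIER[chem.pictogram]
    return total


def score_nemi(inventory: ProcedureInventory) -> NemiProfile:
    """Evaluate the four NEMI greenness criteria for one procedure.

    All criteria are total functions of the inventory: PBT and hazardous-
    list fields are green iff no used chemical carries the flag; the
    corrosivity field is green iff 2 <= pH <= 12; the waste field is green
    iff strictly less than 50 g of waste is produced.
    """
    lo, hi = NEMI_PH_RANGE
    return NemiProfile(
        pbt_ok=not any(c.on_pbt_list for c in inventory.chemicals),
        hazard_ok=not any(c.on_kfpu_list for c in inventory.chemicals),
        corrosive_ok=lo <= inventory.sample_ph <= hi,
        waste_ok=inventory.waste_mass < NEMI_WASTE_LIMIT_G,
    )


def nemi_green_count(profile: NemiProfile) -> int:
    """Number of green fields in a NEMI profile, 0-4."""
    return profile.green_count


def eco_scale(inventory: ProcedureInventory) -> float:
    """Eco-Scale score: 100 minus the sum of penalty points.

    Deliberately not clamped at 0 — a pathological procedure can score
    negative, and clamping would hide differences between very poor
    procedures.
    """
    return 100.0 - sum(pts for _, pts in inventory.penalty_points)


def load_default_penalty_table() -> dict:
    """The editable default Eco-Scale penalty table (JSON package data).

    Adapted from the cited Eco-Scale reference; keys group penalties by
    cause (reagent amount, hazard pictograms, energy, occupational hazard,
    waste amount and treatment).
    """
    with resources.files("greenrank._fixtures").joinpath(
        "eco_scale_penalties.json"
    ).open() as fh:
        table = json.load(fh)
    table.pop("_comment", None)
    return table


def load_name_set(path) -> frozenset[str]:
    """Read a plain-text chemical name set (one name per line, # comments)."""
    names = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.add(line.lower())
    return frozenset(names)


def inventory_from_dict(payload: dict) -> ProcedureInventory:
    """Build an inventory from a plain JSON-style dict."""
    chems = [
        ChemicalUsage(
            c["name"], c["amount"], c.get("pictogram", "none"),
            c.get("on_pbt_list", False), c.get("on_kfpu_list", False),
            c.get("unit", "mL"),
        )
        for c in payload.get("chemicals", [])
    ]
    penalties = [tuple(p) for p in payload.get("penalty_points", [])]
    return ProcedureInventory(
        chemicals=chems,
        sample_ph=payload.get("sample_ph", 7.0),
        waste_mass=payload.get("waste_mass", 0.0),
        penalty_points=penalties,
    )
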