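"""Domain types shared by the diet-quality index scorers.

An :class:`IntakeRecord` holds one participant's daily-equivalent dietary
variables as derived from a food-frequency questionnaire (servings/day,
g/day, mg/day, % of energy, standard drinks).  The three indices read
different subsets of its fields; a table of records round-trips through
:func:`records_to_frame` / :func:`frame_to_records` so the scorers can run
either per record or vectorised over a DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import pandas as pd


class ValidationError(ValueError):
    """An intake or scoring input violates its documented domain."""


class ConfigurationError(ValueError):
    """An unknown component id or invalid scorer configuration."""


#: Field name -> (unit, description).  Shipped as the machine-readable
#: column dictionary for tabular intake files.
COLUMN_DICTIONARY: dict[str, tuple[str, str]] = {
    "participant_id": ("id", "opaque participant identifier"),
    "total_grain_serv": ("servings/day", "total grain (cereal) servings"),
    "wholegrain_serv": ("servings/day", "wholegrain servings"),
    "wholegrain_g": ("g/day", "wholegrain amount (AHEI-2010 anchor 75 g/day)"),
    "vegetable_serv": ("servings/day", "total vegetable servings"),
    "veg_green_serv": ("servings/day", "green vegetable servings (variety evidence)"),
    "veg_orange_serv": ("servings/day", "orange vegetable servings (variety evidence)"),
    "veg_cruciferous_serv": ("servings/day", "cruciferous vegetable servings (variety evidence)"),
    "veg_tuber_bulb_serv": ("servings/day", "tuber/bulb vegetable servings (variety evidence)"),
    "legume_serv": ("servings/day", "legume servings"),
    "fruit_serv": ("servings/day", "fruit servings"),
    "fruit_variety_count": ("count", "number of distinct fruits consumed"),
    "dairy_serv": ("servings/day", "milk and alternatives servings"),
    "meat_protein_serv": ("servings/day", "meat and protein alternatives servings"),
    "discretionary_serv": ("servings/day", "discretionary food servings"),
    "satfat_pct_energy": ("% energy", "energy from saturated fat"),
    "mufa_pufa_serv": ("servings/day", "MUFA and PUFA servings"),
    "sodium_mg": ("mg/day", "sodium intake"),
    "total_sugar_pct_energy": ("% energy", "energy from total sugar"),
    "std_drinks": ("drinks/day", "standard drinks (10 g alcohol each)"),
    "alcohol_g": ("g/day", "alcohol amount"),
    "drinks_per_day": ("drinks/day", "drinks per day (AHEI convention)"),
    "water_proportion": ("fraction", "water/tea/herbal tea/coffee share of beverage intake"),
    "veg_g": ("g/day", "vegetable amount (MDS)"),
    "legume_g": ("g/day", "legume amount (MDS)"),
    "fruit_g": ("g/day", "fruit amount (MDS)"),
    "cereal_g": ("g/day", "cereal amount (MDS)"),
    "fish_g": ("g/day", "fish amount (MDS)"),
    "red_processed_meat_g": ("g/day", "red and processed meat amount (MDS)"),
    "dairy_g": ("g/day", "dairy amount (MDS)"),
    "mufa_g": ("g/day", "monounsaturated fat (MDS lipid-ratio numerator)"),
    "pufa_g": ("g/day", "polyunsaturated fat (MDS lipid-ratio numerator)"),
    "sfa_g": ("g/day", "saturated fat (MDS lipid-ratio denominator)"),
    "nuts_legumes_serv": ("servings/day", "nuts and legumes servings (AHEI)"),
    "ssb_juice_serv": ("servings/day", "sugar-sweetened beverages and fruit juice servings"),
    "red_processed_meat_serv": ("servings/day", "red and processed meat servings (AHEI)"),
    "lc_omega3_mg": ("mg/day", "long-chain omega-3 fats"),
    "pufa_pct_energy": ("% energy", "energy from PUFA"),
    "transfat_pct_energy": ("% energy", "energy from trans fat"),
}

_PCT_FIELDS = frozenset(
    {"satfat_pct_energy", "total_sugar_pct_energy", "pufa_pct_energy", "transfat_pct_energy"}
)
_PROPORTION_FIELDS = frozenset({"water_proportion"})


@dataclass(frozen=True)
class IntakeRecord:
    """One participant's daily-equivalent dietary intake.

    All quantities are non-negative; % energy fields live in [0, 100] and
    ``water_proportion`` in [0, 1].  The vegetable-variety sub-servings are
    variety evidence and need not sum to ``vegetable_serv``.
    """

    participant_id: str
    total_grain_serv: float = 0.0
    wholegrain_serv: float = 0.0
    wholegrain_g: float = 0.0
    vegetable_serv: float = 0.0
    veg_green_serv: float = 0.0
    veg_orange_serv: float = 0.0
    veg_cruciferous_serv: float = 0.0
    veg_tuber_bulb_serv: float = 0.0
    legume_serv: float = 0.0
    fruit_serv: float = 0.0
    fruit_variety_count: int = 0
    dairy_serv: float = 0.0
    meat_protein_serv: float = 0.0
    discretionary_serv: float = 0.0
    satfat_pct_energy: float = 0.0
    mufa_pufa_serv: float = 0.0
    sodium_mg: float = 0.0
    total_sugar_pct_energy: float = 0.0
    std_drinks: float = 0.0
    alcohol_g: float = 0.0
    drinks_per_day: float = 0.0
    water_proportion: float = 0.0
    veg_g: float = 0.0
    legume_g: float = 0.0
    fruit_g: float = 0.0
    cereal_g: float = 0.0
    fish_g: float = 0.0
    red_processed_meat_g: float = 0.0
    dairy_g: float = 0.0
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    sfa_g: float = 1.0
    nuts_legumes_serv: float = 0.0
    ssb_juice_serv: float = 0.0
    red_processed_meat_serv: float = 0.0
    lc_omega3_mg: float = 0.0
    pufa_pct_energy: float = 0.0
    transfat_pct_energy: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "participant_id":
                continue
            value = getattr(self, f.name)
            if value is None or value != value:  # None or NaN
                raise ValidationError(f"{f.name} is missing for {self.participant_id!r}")
            if value < 0:
                raise ValidationError(
                    f"{f.name}={value!r} is negative for {self.participant_id!r}"
                )
            if f.name in _PCT_FIELDS and value > 100:
                raise ValidationError(
                    f"{f.name}={value!r} exceeds 100% energy for {self.participant_id!r}"
                )
            if f.name in _PROPORTION_FIELDS and value > 1:
                raise ValidationError(
                    f"{f.name}={value!r} exceeds 1 for {self.participant_id!r}"
                )


@dataclass(frozen=True)
class ComponentScore:
    """A named component's points and ceiling; 0 <= points <= max_points."""

    component_name: str
    points: float
    max_points: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.points <= self.max_points + 1e-9):
            raise ValidationError(
                f"component {self.component_name!r}: points {self.points} "
                f"outside [0, {self.max_points}]"
            )


@dataclass(frozen=True)
class DQIScore:
    """A diet-quality index total with its per-component breakdown."""

    index_name: str
    total: float
    components: tuple[ComponentScore, ...]

    def __post_init__(self) -> None:
        csum = sum(c.points for c in self.components)
        if abs(csum - self.total) > 1e-9:
            raise ValidationError(
                f"{self.index_name}: total {self.total} != component sum {csum}"
            )

    def component(self, name: str) -> ComponentScore:
        for c in self.components:
            if c.component_name == name:
                return c
        raise KeyError(name)

    def as_dict(self) -> dict[str, float]:
        out = {"total": self.total}
        out.update({c.component_name: c.points for c in self.components})
        return out


INTAKE_COLUMNS = [f.name for f in fields(IntakeRecord)]


def records_to_frame(records: Iterable[IntakeRecord]) -> pd.DataFrame:
    """Stack IntakeRecords into a one-row-per-participant DataFrame."""
    rows = [{name: getattr(r, name) for name in INTAKE_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=INTAKE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[IntakeRecord]:
    """Parse a tabular intake file into validated IntakeRecords.

    Columns must use the names of :data:`COLUMN_DICTIONARY`; missing columns
    default to zero except ``participant_id`` which is required.
    """
    if "participant_id" not in df.columns:
        raise ValidationError("intake table lacks a participant_id column")
    unknown = set(df.columns) - set(INTAKE_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown intake columns: {sorted(unknown)}")
    records = []
    for row in df.to_dict("records"):
        row["participant_id"] = str(row["participant_id"])
        if "fruit_variety_count" in row:
            row["fruit_variety_count"] = int(row["fruit_variety_count"])
        records.append(IntakeRecord(**row))
    return records


def validate_intake_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a wide intake table in place (vectorised counterpart of
    the IntakeRecord invariants); returns the frame for chaining."""
    if "participant_id" not in df.columns:
        raise ValidationError("intake table lacks a participant_id column")
    for col in df.columns:
        if col == "participant_id":
            continue
        s = df[col]
        if (s < 0).any():
            bad = df.loc[s < 0, "participant_id"].iloc[0]
            raise ValidationError(f"{col} negative for participant {bad!r}")
        if col in _PCT_FIELDS and (s > 100).any():
            raise ValidationError(f"{col} exceeds 100% energy")
        if col in _PROPORTION_FIELDS and (s > 1).any():
            raise ValidationError(f"{col} exceeds 1")
    return df
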