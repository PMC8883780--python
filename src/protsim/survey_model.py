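"""Domain model for two-day 24-h recall survey data.

The survey consists of three linked tables: a food composition table
(per-100-g nutrient contents and a food-group label per food item), a
participant table (body weight and analysis weight) and a consumption
table (participant x recall day x food item x grams as consumed).

Participants whose body weight is unknown are retained in the data model
but flagged excluded: every analysis operation refuses to touch them, so
the exclusion is auditable rather than silent.  A recall day on which a
participant consumed nothing is representable: day declaration is kept
separate from the consumption records, which distinguishes "zero intake"
from "no data".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Nutrient key that must be present for every food item (g per 100 g).
PROTEIN = "protein_g"

#: Recall days of the two-day design.
DAYS = (1, 2)


class SurveyValidationError(ValueError):
    """Raised when survey inputs violate a structural invariant."""


class ExcludedParticipantError(ValueError):
    """Raised when an analysis operation is asked about an excluded participant."""


@dataclass(frozen=True)
class FoodItem:
    """One food item of the composition table.

    ``nutrients`` maps nutrient name to amount per 100 g edible portion;
    protein (``protein_g``) is mandatory, everything else optional.
    """

    food_code: str
    name: str
    group: str
    nutrients: Mapping[str, float]

    def __post_init__(self) -> None:
        if PROTEIN not in self.nutrients:
            raise SurveyValidationError(
                f"food {self.food_code!r} has no {PROTEIN} entry"
            )
        for nut, amount in self.nutrients.items():
            if not math.isfinite(amount) or amount < 0:
                raise SurveyValidationError(
                    f"food {self.food_code!r}: nutrient {nut!r} amount "
                    f"{amount!r} must be finite and >= 0"
                )

    @property
    def protein_per_100g(self) -> float:
        return float(self.nutrients[PROTEIN])

    def nutrient(self, name: str) -> float:
        """Amount of ``name`` per 100 g; missing nutrients are an error, never 0."""
        try:
            return float(self.nutrients[name])
        except KeyError:
            raise SurveyValidationError(
                f"nutrient {name!r} not recorded for food {self.food_code!r}"
            ) from None


class FoodCompositionTable:
    """Lookup of :class:`FoodItem` by food code, with group views."""

    def __init__(self, items: Iterable[FoodItem]):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            if item.food_code in self._items:
                raise SurveyValidationError(
                    f"duplicate food_code {item.food_code!r} in composition table"
                )
            self._items[item.food_code] = item

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._items

    def __getitem__(self, food_code: str) -> FoodItem:
        try:
            return self._items[food_code]
        except KeyError:
            raise SurveyValidationError(
                f"unknown food_code {food_code!r}"
            ) from None

    @property
    def groups(self) -> set[str]:
        return {item.group for item in self._items.values()}

    def group_items(self, group: str) -> list[FoodItem]:
        """All items carrying ``group``, in insertion order."""
        return [item for item in self._items.values() if item.group == group]

    def nutrient_names(self) -> set[str]:
        names: set[str] = set()
        for item in self._items.values():
            names.update(item.nutrients)
        return names


@dataclass(frozen=True)
class Participant:
    participant_id: str
    body_weight_kg: float | None
    analysis_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.body_weight_kg is not None and not self.body_weight_kg > 0:
            raise SurveyValidationError(
                f"participant {self.participant_id!r}: body weight must be "
                f"positive or missing, got {self.body_weight_kg!r}"
            )
        if not self.analysis_weight > 0:
            raise SurveyValidationError(
                f"participant {self.participant_id!r}: analysis weight must be "
                f"> 0, got {self.analysis_weight!r}"
            )

    @property
    def excluded(self) -> bool:
        """True when body weight is unknown; barred from every analysis."""
        return self.body_weight_kg is None


@dataclass(frozen=True)
class ConsumptionRecord:
    participant_id: str
    day_index: int
    food_code: str
    grams: float

    def __post_init__(self) -> None:
        if self.day_index not in DAYS:
            raise SurveyValidationError(
                f"day_index must be one of {DAYS}, got {self.day_index!r}"
            )
        if not (math.isfinite(self.grams) and self.grams >= 0):
            raise SurveyValidationError(
                f"grams must be finite and >= 0, got {self.grams!r}"
            )


@dataclass
class Survey:
    """A validated survey: participants, consumption records, composition.

    ``declared_days`` records which recall days exist for each participant
    even when nothing was consumed on them; it defaults to both days of
    the two-day design for every participant.
    """

    participants: dict[str, Participant]
    records: list[ConsumptionRecord]
    composition: FoodCompositionTable
    declared_days: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.declared_days:
            self.declared_days = {
                pid: frozenset(DAYS) for pid in self.participants
            }
        self.validate()

    def validate(self) -> None:
        for rec in self.records:
            if rec.participant_id not in self.participants:
                raise SurveyValidationError(
                    f"record cites unknown participant {rec.participant_id!r}"
                )
            if rec.food_code not in self.composition:
                raise SurveyValidationError(
                    f"record cites unknown food_code {rec.food_code!r}"
                )
            if rec.day_index not in self.declared_days.get(
                rec.participant_id, frozenset()
            ):
                raise SurveyValidationError(
                    f"record for participant {rec.participant_id!r} on "
                    f"undeclared day {rec.day_index}"
                )
        for pid, p in self.participants.items():
            days = self.declared_days.get(pid, frozenset())
            if not p.excluded and days != frozenset(DAYS):
                raise SurveyValidationError(
                    f"participant {pid!r} must declare exactly days {DAYS}, "
                    f"has {sorted(days)}"
                )

    # -- convenience views -------------------------------------------------

    def participant(self, participant_id: str) -> Participant:
        try:
            return self.participants[participant_id]
        except KeyError:
            raise SurveyValidationError(
                f"unknown participant {participant_id!r}"
            ) from None

    def included_ids(self) -> list[str]:
        """Participant ids analysable (known body weight), in table order."""
        return [pid for pid, p in self.participants.items() if not p.excluded]

    def records_for(self, participant_id: str, day_index: int | None = None):
        for rec in self.records:
            if rec.participant_id != participant_id:
                continue
            if day_index is not None and rec.day_index != day_index:
                continue
            yield rec

    def copy_with_records(self, records: Sequence[ConsumptionRecord]) -> "Survey":
        return Survey(
            participants=dict(self.participants),
            records=list(records),
            composition=self.composition,
            declared_days=dict(self.declared_days),
        )


# ---------------------------------------------------------------------------
# Intake computation
# ---------------------------------------------------------------------------


def _check_analysable(survey: Survey, participant_id: str, day_index: int | None):
    p = survey.participant(participant_id)
    if p.excluded:
        raise ExcludedParticipantError(
            f"participant {participant_id!r} is excluded (unknown body weight)"
        )
    if day_index is not None and day_index not in survey.declared_days[participant_id]:
        raise SurveyValidationError(
            f"day {day_index} not declared for participant {participant_id!r}"
        )
    return p


def daily_protein_per_kg(survey: Survey, participant_id: str, day_index: int) -> float:
    """Protein intake on one recall day, in g per kg body weight.

    Sum over the day's records of grams x protein-per-100-g / 100, divided
    by the participant's body weight.
    """
    p = _check_analysable(survey, participant_id, day_index)
    grams_protein = sum(
        rec.grams * survey.composition[rec.food_code].protein_per_100g / 100.0
        for rec in survey.records_for(participant_id, day_index)
    )
    return grams_protein / p.body_weight_kg


def mean_protein_per_kg(survey: Survey, participant_id: str) -> float:
    """Protein intake averaged over the two recall days, g/kg BW/d."""
    _check_analysable(survey, participant_id, None)
    days = sorted(survey.declared_days[participant_id])
    vals = [daily_protein_per_kg(survey, participant_id, d) for d in days]
    return sum(vals) / len(vals)


def total_nutrient_per_day(
    survey: Survey, participant_id: str, day_index: int, nutrient: str
) -> float:
    """Total intake of ``nutrient`` on one recall day, in the nutrient's units.

    Missing nutrient entries raise; they are never treated as zero.
    """
    _check_analysable(survey, participant_id, day_index)
    return sum(
        rec.grams * survey.composition[rec.food_code].nutrient(nutrient) / 100.0
        for rec in survey.records_for(participant_id, day_index)
    )


# ---------------------------------------------------------------------------
# Scenario definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioDefinition:
    """One replacement scenario: ordered (food group -> alternative food).

    The alternative of each group must exist in the composition table,
    belong to the group it serves, and have a protein content strictly
    above the group's P75 threshold; that last check needs the threshold
    machinery and lives in :func:`protsim.scenario_engine.validate_scenario`.
    """

    scenario_id: str
    replacements: tuple[tuple[str, str], ...]
    eligibility_cutoff: float = 1.0

    def __post_init__(self) -> None:
        groups = [g for g, _ in self.replacements]
        if len(groups) != len(set(groups)):
            raise SurveyValidationError(
                f"scenario {self.scenario_id!r}: duplicate groups in replacements"
            )
        if not self.eligibility_cutoff > 0:
            raise SurveyValidationError("eligibility_cutoff must be positive")

    @property
    def groups(self) -> list[str]:
        return [g for g, _ in self.replacements]

    def alternative_for(self, group: str) -> str:
        for g, code in self.replacements:
            if g == group:
                return code
        raise KeyError(group)


def read_scenario(path: str | Path) -> ScenarioDefinition:
    """Read a scenario definition from YAML (JSON is a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        reps = tuple(
            (str(entry["group"]), str(entry["alternative_food_code"]))
            for entry in raw["replacements"]
        )
        return ScenarioDefinition(
            scenario_id=str(raw["scenario_id"]),
            replacements=reps,
            eligibility_cutoff=float(raw.get("eligibility_cutoff", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise SurveyValidationError(f"malformed scenario file {path}: {exc}") from exc


def write_scenario(scenario: ScenarioDefinition, path: str | Path) -> None:
    doc = {
        "scenario_id": scenario.scenario_id,
        "eligibility_cutoff": scenario.eligibility_cutoff,
        "replacements": [
            {"group": g, "alternative_food_code": c}
            for g, c in scenario.replacements
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------


def read_composition(path: str | Path) -> FoodCompositionTable:
    """Composition CSV: food_code, name, group, then ``<nutrient>_per_100g`` columns."""
    df = pd.read_csv(path, dtype={"food_code": str, "name": str, "group": str})
    required = {"food_code", "name", "group"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyValidationError(
            f"composition file {path} lacks columns {sorted(missing)}"
        )
    suffix = "_per_100g"
    nutrient_cols = {
        col: col[: -len(suffix)] for col in df.columns if col.endswith(suffix)
    }
    if PROTEIN not in nutrient_cols.values():
        raise SurveyValidationError(
            f"composition file {path} lacks mandatory column {PROTEIN}{suffix}"
        )
    items = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        nutrients = {
            name: float(row_d[col])
            for col, name in nutrient_cols.items()
            if pd.notna(row_d[col])
        }
        items.append(
            FoodItem(
                food_code=str(row_d["food_code"]),
                name=str(row_d["name"]),
                group=str(row_d["group"]),
                nutrients=nutrients,
            )
        )
    return FoodCompositionTable(items)


def read_survey(
    composition_path: str | Path,
    participants_path: str | Path,
    records_path: str | Path,
) -> Survey:
    """Read and validate a survey from its three CSV files.

    Participants with an empty body-weight field are retained but flagged
    excluded.  Both recall days are declared for every participant (the
    two-day design); an empty day therefore reads back as zero intake.
    """
    composition = read_composition(composition_path)

    pdf = pd.read_csv(participants_path, dtype={"participant_id": str})
    if pdf["participant_id"].duplicated().any():
        dup = pdf.loc[pdf["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise SurveyValidationError(f"duplicate participant_id {dup!r}")
    participants = {}
    for row in pdf.itertuples(index=False):
        bw = None if pd.isna(row.body_weight_kg) else float(row.body_weight_kg)
        participants[str(row.participant_id)] = Participant(
            participant_id=str(row.participant_id),
            body_weight_kg=bw,
            analysis_weight=float(row.analysis_weight),
        )

    rdf = pd.read_csv(
        records_path, dtype={"participant_id": str, "food_code": str}
    )
    records = [
        ConsumptionRecord(
            participant_id=str(row.participant_id),
            day_index=int(row.day_index),
            food_code=str(row.food_code),
            grams=float(row.grams),
        )
        for row in rdf.itertuples(index=False)
    ]
    return Survey(participants=participants, records=records, composition=composition)


def write_survey(
    survey: Survey,
    composition_path: str | Path,
    participants_path: str | Path,
    records_path: str | Path,
) -> None:
    """Write the three survey CSVs; inverse of :func:`read_survey`.

    Floats are rendered with :func:`repr` precision so a read/write
    round-trip preserves every numeric field exactly.
    """
    def fmt(x) -> str:
        return "" if x is None else repr(float(x))

    nutrient_names = sorted(survey.composition.nutrient_names())
    comp_rows = []
    for item in survey.composition:
        row = {"food_code": item.food_code, "name": item.name, "group": item.group}
        for nut in nutrient_names:
            row[f"{nut}_per_100g"] = fmt(item.nutrients.get(nut))
        comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(composition_path, index=False)

    part_rows = [
        {
            "participant_id": p.participant_id,
            "body_weight_kg": fmt(p.body_weight_kg),
            "analysis_weight": fmt(p.analysis_weight),
        }
        for p in survey.participants.values()
    ]
    pd.DataFrame(part_rows).to_csv(participants_path, index=False)

    rec_rows = [
        {
            "participant_id": r.participant_id,
            "day_index": r.day_index,
            "food_code": r.food_code,
            "grams": fmt(r.grams),
        }
        for r in survey.records
    ]
    pd.DataFrame(
        rec_rows, columns=["participant_id", "day_index", "food_code", "grams"]
    ).to_csv(records_path, index=False)
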