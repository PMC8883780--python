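"""Food-replacement scenario simulation.

Within each treated food group, every consumed food whose protein content
lies strictly below the group's 75th percentile (P75) of per-item protein
contents is replaced, gram for gram, by the group's designated
high-protein alternative (whose protein content must strictly exceed the
P75).  Replacements are confined to participants whose baseline two-day
mean protein intake is below an eligibility cut-off (default 1.0 g/kg
body weight per day); eligibility is frozen at baseline and never
re-evaluated during substitution, so the pass is one-shot and idempotent.

The P75 threshold is, by default, computed over the distinct food items
of the composition table in that group, each counted once and unweighted
by consumption; a consumption-based dialect (percentile over the distinct
foods actually consumed in the survey) is available via ``p75_basis``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survey_model import (
    ConsumptionRecord,
    FoodCompositionTable,
    ScenarioDefinition,
    Survey,
    SurveyValidationError,
    mean_protein_per_kg,
    total_nutrient_per_day,
)

P75_BASES = ("items", "consumption")


@dataclass(frozen=True)
class GroupThreshold:
    """P75 of per-item protein contents within one food group."""

    group: str
    p75_protein_per_100g: float
    n_items: int


@dataclass(frozen=True)
class ReplacementEntry:
    participant_id: str
    day_index: int
    group: str
    from_food_code: str
    to_food_code: str
    grams: float
    protein_delta_g: float


@dataclass
class ReplacementLog:
    """Audit trail: one entry per substituted consumption record."""

    entries: list[ReplacementEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "participant_id",
            "day_index",
            "group",
            "from_food_code",
            "to_food_code",
            "grams",
            "protein_delta_g",
        ]
        return pd.DataFrame([e.__dict__ for e in self.entries], columns=cols)


@dataclass
class ScenarioResult:
    modified_survey: Survey
    log: ReplacementLog
    scenario: ScenarioDefinition
    thresholds: dict[str, GroupThreshold]
    eligible: frozenset[str]


def compute_p75(
    composition: FoodCompositionTable,
    group: str,
    *,
    basis: str = "items",
    survey: Survey | None = None,
) -> GroupThreshold:
    """75th percentile of protein contents in a food group.

    ``basis='items'`` uses every distinct item of the composition table in
    that group; ``basis='consumption'`` restricts to the distinct foods
    actually appearing in the survey's consumption records (and then needs
    ``survey``).  The percentile uses the linear-interpolation definition:
    with sorted values x(1..n), the value at position 1 + 0.75(n-1).
    """
    if basis not in P75_BASES:
        raise SurveyValidationError(f"p75 basis must be one of {P75_BASES}")
    items = composition.group_items(group)
    if basis == "consumption":
        if survey is None:
            raise SurveyValidationError("consumption-based P75 needs the survey")
        consumed = {r.food_code for r in survey.records}
        items = [it for it in items if it.food_code in consumed]
    if not items:
        raise SurveyValidationError(
            f"no items available for group {group!r} (basis={basis!r})"
        )
    values = np.array([it.protein_per_100g for it in items], dtype=float)
    p75 = float(np.percentile(values, 75))  # linear interpolation
    return GroupThreshold(group=group, p75_protein_per_100g=p75, n_items=len(items))


def validate_scenario(
    survey: Survey, scenario: ScenarioDefinition, *, p75_basis: str = "items"
) -> dict[str, GroupThreshold]:
    """Check a scenario against the composition table; return the thresholds.

    Every treated group must exist; each alternative must exist, belong to
    its group, and carry strictly more protein than the group's P75.
    """
    comp = survey.composition
    thresholds: dict[str, GroupThreshold] = {}
    for group, alt_code in scenario.replacements:
        if group not in comp.groups:
            raise SurveyValidationError(
                f"scenario {scenario.scenario_id!r}: group {group!r} absent "
                f"from composition table"
            )
        alt = comp[alt_code]
        if alt.group != group:
            raise SurveyValidationError(
                f"scenario {scenario.scenario_id!r}: alternative {alt_code!r} "
                f"belongs to group {alt.group!r}, not {group!r}"
            )
        thr = compute_p75(comp, group, basis=p75_basis, survey=survey)
        if not alt.protein_per_100g > thr.p75_protein_per_100g:
            raise SurveyValidationError(
                f"scenario {scenario.scenario_id!r}: alternative {alt_code!r} "
                f"protein {alt.protein_per_100g} g/100g does not exceed the "
                f"group P75 of {thr.p75_protein_per_100g} g/100g"
            )
        thresholds[group] = thr
    return thresholds


def eligible_participants(survey: Survey, cutoff: float = 1.0) -> frozenset[str]:
    """Non-excluded participants with two-day mean protein intake strictly
    below ``cutoff`` g/kg BW/d; those at or above the cut-off are left out."""
    return frozenset(
        pid
        for pid in survey.included_ids()
        if mean_protein_per_kg(survey, pid) < cutoff
    )


def apply_scenario(
    survey: Survey, scenario: ScenarioDefinition, *, p75_basis: str = "items"
) -> ScenarioResult:
    """Run one replacement scenario over a survey.

    Eligibility is determined once, on the original survey.  For each
    consumption record of an eligible participant whose food belongs to a
    treated group and whose protein content is strictly below the group's
    P75, the food code is rewritten to the group's alternative; grams are
    unchanged, so every nutrient of that record now comes from the
    alternative's composition row.  Everything else is untouched.
    """
    thresholds = validate_scenario(survey, scenario, p75_basis=p75_basis)
    eligible = eligible_participants(survey, scenario.eligibility_cutoff)
    comp = survey.composition

    log = ReplacementLog()
    new_records: list[ConsumptionRecord] = []
    for rec in survey.records:
        item = comp[rec.food_code]
        if (
            rec.participant_id in eligible
            and item.group in thresholds
            and item.protein_per_100g < thresholds[item.group].p75_protein_per_100g
        ):
            alt_code = scenario.alternative_for(item.group)
            alt = comp[alt_code]
            delta = rec.grams * (alt.protein_per_100g - item.protein_per_100g) / 100.0
            log.entries.append(
                ReplacementEntry(
                    participant_id=rec.participant_id,
                    day_index=rec.day_index,
                    group=item.group,
                    from_food_code=rec.food_code,
                    to_food_code=alt_code,
                    grams=rec.grams,
                    protein_delta_g=delta,
                )
            )
            new_records.append(replace(rec, food_code=alt_code))
        else:
            new_records.append(rec)

    return ScenarioResult(
        modified_survey=survey.copy_with_records(new_records),
        log=log,
        scenario=scenario,
        thresholds=thresholds,
        eligible=eligible,
    )


def count_replacements(result: ScenarioResult) -> tuple[dict[str, int], int]:
    """Number of substituted records per treated group, plus the total."""
    counts = {group: 0 for group in result.scenario.groups}
    for entry in result.log.entries:
        counts[entry.group] += 1
    return counts, len(result.log)


def group_contributions(result: ScenarioResult) -> list[tuple[str, float]]:
    """Per-group mean protein increase, g/d, sorted descending.

    For each group, the analysis-weighted population mean -- over ALL
    non-excluded participants, on the two-day-average basis -- of the
    protein gained from that group's replacements.  Ties are broken by
    group label so the ranking is deterministic.
    """
    survey = result.modified_survey
    included = survey.included_ids()
    weights = {pid: survey.participants[pid].analysis_weight for pid in included}
    total_w = sum(weights.values())
    n_days = len(survey.declared_days[included[0]]) if included else 2

    per_group: dict[str, float] = {group: 0.0 for group in result.scenario.groups}
    for entry in result.log.entries:
        if entry.participant_id in weights:
            per_group[entry.group] += (
                weights[entry.participant_id] * entry.protein_delta_g
            )
    contributions = {
        group: tot / (n_days * total_w) if total_w else 0.0
        for group, tot in per_group.items()
    }
    return sorted(contributions.items(), key=lambda kv: (-kv[1], kv[0]))


def derive_combined_scenario(
    result_rich: ScenarioResult,
    result_enriched: ScenarioResult,
    k: int = 3,
    *,
    scenario_id: str = "combined",
) -> ScenarioDefinition:
    """Build the combined scenario from two ranked scenario results.

    Takes the top ``k`` contributing groups of the protein-enriched
    scenario (with that scenario's alternatives), then walks the
    protein-rich scenario's contribution ranking from the top, skipping
    any group already selected, until ``k`` further groups are added (with
    the protein-rich scenario's alternatives); the result treats exactly
    ``2k`` groups.
    """
    ranking_enriched = [g for g, _ in group_contributions(result_enriched)]
    ranking_rich = [g for g, _ in group_contributions(result_rich)]
    available = set(ranking_enriched) | set(ranking_rich)
    if len(available) < 2 * k:
        raise SurveyValidationError(
            f"need at least {2 * k} distinct groups across both scenarios, "
            f"have {len(available)}"
        )

    picks: list[tuple[str, str]] = []
    for group in ranking_enriched[:k]:
        picks.append((group, result_enriched.scenario.alternative_for(group)))
    chosen = {g for g, _ in picks}
    for group in ranking_rich:
        if len(picks) >= 2 * k:
            break
        if group in chosen:
            continue
        picks.append((group, result_rich.scenario.alternative_for(group)))
        chosen.add(group)
    if len(picks) < 2 * k:
        raise SurveyValidationError(
            f"ranking walk exhausted after {len(picks)} groups; need {2 * k}"
        )
    return ScenarioDefinition(
        scenario_id=scenario_id,
        replacements=tuple(picks),
        eligibility_cutoff=result_enriched.scenario.eligibility_cutoff,
    )


def mean_nutrient_intakes(
    survey: Survey, nutrients: list[str]
) -> pd.DataFrame:
    """Analysis-weighted mean and sd of daily nutrient intakes.

    Per participant, the two-day average daily intake of each requested
    nutrient; then the weighted mean and weighted standard deviation over
    all non-excluded participants.  The sd uses the weighted population
    formula (denominator = sum of weights).
    """
    included = survey.included_ids()
    if not included:
        raise SurveyValidationError("no analysable participants")
    w = np.array([survey.participants[pid].analysis_weight for pid in included])
    rows = []
    for nutrient in nutrients:
        x = np.array(
            [
                np.mean(
                    [
                        total_nutrient_per_day(survey, pid, d, nutrient)
                        for d in sorted(survey.declared_days[pid])
                    ]
                )
                for pid in included
            ]
        )
        mean = float(np.average(x, weights=w))
        sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))
        rows.append({"nutrient": nutrient, "weighted_mean": mean, "weighted_sd": sd})
    return pd.DataFrame(rows).set_index("nutrient")
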