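import numpy as np
import pytest

import protsim as ps
from protsim.scenario_engine import (
    GroupThreshold,
    ReplacementEntry,
    ReplacementLog,
    ScenarioResult,
)

from conftest import make_item, make_survey, random_small_survey


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_p75(values):
    """Sort-and-interpolate 75th percentile: position 1 + 0.75 (n - 1)."""
    xs = sorted(values)
    n = len(xs)
    pos = 0.75 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def oracle_apply(survey, scenario):
    """Record-by-record re-implementation of the replacement pass."""
    comp = survey.composition
    p75 = {}
    for group, _alt in scenario.replacements:
        p75[group] = oracle_p75(
            [it.protein_per_100g for it in comp.group_items(group)]
        )
    eligible = set()
    for pid, p in survey.participants.items():
        if p.excluded:
            continue
        total = {1: 0.0, 2: 0.0}
        for rec in survey.records:
            if rec.participant_id == pid:
                total[rec.day_index] += (
                    rec.grams * comp[rec.food_code].protein_per_100g / 100.0
                )
        mean = (total[1] + total[2]) / 2.0 / p.body_weight_kg
        if mean < scenario.eligibility_cutoff:
            eligible.add(pid)
    out = []
    for rec in survey.records:
        item = comp[rec.food_code]
        if (
            rec.participant_id in eligible
            and item.group in p75
            and item.protein_per_100g < p75[item.group]
        ):
            out.append(
                ps.ConsumptionRecord(
                    rec.participant_id,
                    rec.day_index,
                    scenario.alternative_for(item.group),
                    rec.grams,
                )
            )
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# P75 threshold
# ---------------------------------------------------------------------------


class TestComputeP75:
    def test_linear_interpolation_five_values(self):
        comp = ps.FoodCompositionTable(
            [make_item(f"f{i}", "g", float(v)) for i, v in enumerate([1, 2, 3, 4, 5])]
        )
        thr = ps.compute_p75(comp, "g")
        assert thr.p75_protein_per_100g == pytest.approx(4.0)
        assert thr.n_items == 5

    def test_single_item_group(self):
        comp = ps.FoodCompositionTable([make_item("f", "g", 7.2)])
        assert ps.compute_p75(comp, "g").p75_protein_per_100g == pytest.approx(7.2)

    def test_all_equal_group_yields_no_replacements(self):
        items = [(f"f{i}", "g", 3.0) for i in range(4)] + [("alt", "g", 9.0)]
        s = make_survey(items, [("p1", 70.0, 1.0)], [("p1", 1, "f0", 100.0)])
        # P75 over [3,3,3,3,9] is 4.5 > 3: the equal items ARE below it, so
        # use a table of only the equal items to exercise the degenerate case
        comp = ps.FoodCompositionTable([make_item(f"e{i}", "h", 3.0) for i in range(4)])
        thr = ps.compute_p75(comp, "h")
        assert thr.p75_protein_per_100g == pytest.approx(3.0)
        # no item is strictly below 3.0, so none would be replaced

    def test_empty_group_is_error(self):
        comp = ps.FoodCompositionTable([make_item("f", "g", 1.0)])
        with pytest.raises(ps.SurveyValidationError):
            ps.compute_p75(comp, "nonexistent")

    def test_matches_oracle_on_random_vectors(self):
        """1000 random vectors with ties and n = 1 against the
        sort-and-interpolate definition."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            vals = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            if rng.random() < 0.5:
                vals = rng.uniform(0, 30, size=n)
            comp = ps.FoodCompositionTable(
                [make_item(f"f{i}", "g", float(v)) for i, v in enumerate(vals)]
            )
            got = ps.compute_p75(comp, "g").p75_protein_per_100g
            assert got == pytest.approx(oracle_p75(vals), rel=1e-12, abs=1e-12)

    def test_consumption_basis_restricts_to_consumed_foods(self):
        items = [("a", "g", 1.0), ("b", "g", 2.0), ("c", "g", 3.0), ("d", "g", 40.0)]
        s = make_survey(
            items, [("p1", 70.0, 1.0)], [("p1", 1, "a", 50.0), ("p1", 2, "b", 50.0)]
        )
        thr = ps.compute_p75(s.composition, "g", basis="consumption", survey=s)
        assert thr.n_items == 2
        assert thr.p75_protein_per_100g == pytest.approx(oracle_p75([1.0, 2.0]))


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


class TestEligibility:
    def test_strictly_below_cutoff_included(self, basic_survey):
        # p1 mean is well below 1.0; p2 sits exactly at 1.0 and is excluded
        assert ps.mean_protein_per_kg(basic_survey, "p2") == pytest.approx(1.0)
        assert ps.eligible_participants(basic_survey, 1.0) == {"p1"}

    def test_all_above_cutoff_means_no_replacements(self):
        items = [("lo", "g", 5.0), ("hi", "g", 20.0)]
        s = make_survey(
            items,
            [("p1", 50.0, 1.0)],
            [("p1", 1, "hi", 500.0), ("p1", 2, "hi", 500.0)],
        )
        assert ps.eligible_participants(s, 1.0) == frozenset()
        sc = ps.ScenarioDefinition("s", (("g", "hi"),))
        res = ps.apply_scenario(s, sc)
        assert len(res.log) == 0
        assert res.modified_survey.records == s.records


# ---------------------------------------------------------------------------
# apply_scenario
# ---------------------------------------------------------------------------


def _p75_fixture():
    # group with P75 = 4.0 over [1,2,3,4,9]: position 1+0.75*4 = 4 -> 4.0
    items = [
        ("f1", "g", 1.0),
        ("f2", "g", 2.0),
        ("f3", "g", 3.0),
        ("f4", "g", 4.0),
        ("alt", "g", 9.0),
    ]
    participants = [("elig", 80.0, 1.0), ("inel", 50.0, 1.0)]
    records = [
        ("elig", 1, "f3", 150.0),
        ("elig", 2, "f4", 150.0),  # exactly at P75
        ("inel", 1, "f3", 150.0),
        ("inel", 1, "alt", 700.0),
        ("inel", 2, "alt", 700.0),
    ]
    s = make_survey(items, participants, records)
    sc = ps.ScenarioDefinition("s", (("g", "alt"),), 1.0)
    return s, sc


class TestApplyScenario:
    def test_worked_replacement_arithmetic(self):
        s, sc = _p75_fixture()
        res = ps.apply_scenario(s, sc)
        assert res.thresholds["g"].p75_protein_per_100g == pytest.approx(4.0)
        # only the eligible participant's 3 g/100g record is replaced
        assert len(res.log) == 1
        e = res.log.entries[0]
        assert (e.participant_id, e.from_food_code, e.to_food_code) == (
            "elig", "f3", "alt",
        )
        assert e.grams == 150.0
        # protein 150 g x (9-3)/100 = +9 g; record goes 4.5 -> 13.5 g
        assert e.protein_delta_g == pytest.approx(9.0)
        after = ps.total_nutrient_per_day(res.modified_survey, "elig", 1, "protein_g")
        assert after == pytest.approx(13.5)

    def test_boundary_food_at_p75_untouched(self):
        s, sc = _p75_fixture()
        res = ps.apply_scenario(s, sc)
        day2 = list(res.modified_survey.records_for("elig", 2))
        assert day2 == list(s.records_for("elig", 2))  # f4 at P75 stays

    def test_ineligible_participant_untouched(self):
        s, sc = _p75_fixture()
        res = ps.apply_scenario(s, sc)
        assert list(res.modified_survey.records_for("inel")) == list(
            s.records_for("inel")
        )

    def test_alternative_must_exceed_p75(self):
        items = [("f1", "g", 1.0), ("f2", "g", 2.0), ("f3", "g", 3.0)]
        s = make_survey(items, [("p1", 70.0, 1.0)], [])
        sc = ps.ScenarioDefinition("s", (("g", "f2"),))
        with pytest.raises(ps.SurveyValidationError, match="does not exceed"):
            ps.apply_scenario(s, sc)

    def test_unknown_group_is_error(self):
        s, _ = _p75_fixture()
        sc = ps.ScenarioDefinition("s", (("ghosts", "alt"),))
        with pytest.raises(ps.SurveyValidationError, match="ghosts"):
            ps.apply_scenario(s, sc)

    def test_matches_bruteforce_oracle_on_random_surveys(self):
        """200 seeded random small surveys: the engine and an independent
        record-by-record re-implementation agree exactly."""
        rng = np.random.default_rng(2024)
        tested = 0
        while tested < 200:
            survey, scenario = random_small_survey(rng)
            if scenario is None:
                continue
            res = ps.apply_scenario(survey, scenario)
            assert res.modified_survey.records == oracle_apply(survey, scenario)
            tested += 1

    def test_invariants_on_random_surveys(self):
        """Gram conservation, strict protein increase, idempotence and
        monotone fraction-below on seeded fixtures."""
        rng = np.random.default_rng(77)
        tested = 0
        while tested < 60:
            survey, scenario = random_small_survey(rng)
            if scenario is None:
                continue
            res = ps.apply_scenario(survey, scenario)
            # gram conservation per participant-day
            for pid in survey.participants:
                for day in (1, 2):
                    before = sum(r.grams for r in survey.records_for(pid, day))
                    after = sum(
                        r.grams for r in res.modified_survey.records_for(pid, day)
                    )
                    assert after == before
            # strict per-record protein increase
            for e in res.log.entries:
                if e.grams > 0:
                    assert e.protein_delta_g > 0
            # eligible participants never lose protein; ineligible untouched
            eligible = res.eligible
            for pid in survey.included_ids():
                b = ps.mean_protein_per_kg(survey, pid)
                a = ps.mean_protein_per_kg(res.modified_survey, pid)
                if pid in eligible:
                    assert a >= b
                else:
                    assert a == b
            # population fraction below cutoff cannot increase
            def frac(s):
                ids = s.included_ids()
                return np.mean([ps.mean_protein_per_kg(s, p) < 1.0 for p in ids])
            if survey.included_ids():
                assert frac(res.modified_survey) <= frac(survey)
            # one-pass idempotence
            res2 = ps.apply_scenario(res.modified_survey, scenario)
            assert len(res2.log) == 0
            assert res2.modified_survey.records == res.modified_survey.records
            tested += 1


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


class TestAccounting:
    def test_count_replacements_empty_and_manual(self):
        s, sc = _p75_fixture()
        res = ps.apply_scenario(s, sc)
        counts, total = ps.count_replacements(res)
        assert counts == {"g": 1} and total == 1

    def test_counts_match_independent_groupby(self):
        rng = np.random.default_rng(5)
        tested = 0
        while tested < 20:
            survey, scenario = random_small_survey(rng)
            if scenario is None:
                continue
            res = ps.apply_scenario(survey, scenario)
            counts, total = ps.count_replacements(res)
            df = res.log.to_frame()
            recount = df.groupby("group").size().to_dict() if len(df) else {}
            for g, c in counts.items():
                assert c == recount.get(g, 0)
            assert total == len(res.log.entries) == sum(counts.values())
            tested += 1

    def test_single_entry_contribution_formula(self):
        # one +9 g replacement among N=4 equally weighted participants,
        # 2-day basis -> contribution 9 / (2*4) g/d
        items = [
            ("f1", "g", 1.0), ("f2", "g", 2.0), ("f3", "g", 3.0),
            ("f4", "g", 4.0), ("alt", "g", 9.0), ("other", "h", 30.0),
        ]
        participants = [(f"p{i}", 70.0, 1.0) for i in range(4)]
        records = [("p0", 1, "f3", 150.0)] + [
            (f"p{i}", d, "other", 400.0) for i in (1, 2, 3) for d in (1, 2)
        ]
        s = make_survey(items, participants, records)
        res = ps.apply_scenario(s, ps.ScenarioDefinition("s", (("g", "alt"),)))
        assert len(res.log) == 1
        contrib = dict(ps.group_contributions(res))
        assert contrib["g"] == pytest.approx(9.0 / 8.0)

    def test_contributions_sum_to_population_mean_protein_gain(self):
        rng = np.random.default_rng(9)
        tested = 0
        while tested < 20:
            survey, scenario = random_small_survey(rng)
            if scenario is None or not survey.included_ids():
                continue
            res = ps.apply_scenario(survey, scenario)
            ids = survey.included_ids()
            w = np.array([survey.participants[p].analysis_weight for p in ids])

            def mean_protein_g_per_day(s):
                x = np.array([
                    np.mean([
                        ps.total_nutrient_per_day(s, p, d, "protein_g")
                        for d in (1, 2)
                    ])
                    for p in ids
                ])
                return np.average(x, weights=w)

            gain = mean_protein_g_per_day(res.modified_survey) - mean_protein_g_per_day(survey)
            total_contrib = sum(c for _, c in ps.group_contributions(res))
            assert total_contrib == pytest.approx(gain, abs=1e-9)
            tested += 1


# ---------------------------------------------------------------------------
# Combined-scenario derivation
# ---------------------------------------------------------------------------


def _result_with_ranking(survey, scenario_id, group_alts, deltas):
    """Fabricate a ScenarioResult whose contribution ranking follows
    ``deltas`` (group -> total logged protein gain for participant p1)."""
    sc = ps.ScenarioDefinition(scenario_id, tuple(group_alts), 1.0)
    log = ReplacementLog(
        [
            ReplacementEntry("p1", 1, g, "x", "y", 100.0, d)
            for g, d in deltas.items()
        ]
    )
    return ScenarioResult(
        modified_survey=survey,
        log=log,
        scenario=sc,
        thresholds={},
        eligible=frozenset({"p1"}),
    )


GROUPS6 = [
    "bread",
    "yoghurt, cream desserts and pudding",
    "soups",
    "potatoes, vegetables and legumes",
    "non-alcoholic beverages and milk",
    "savoury spreads, sweet spreads and cheese",
]


@pytest.fixture
def ranking_survey():
    items = [(f"i{k}", g, 5.0) for k, g in enumerate(GROUPS6)] + [
        (f"a{k}", g, 20.0) for k, g in enumerate(GROUPS6)
    ]
    return make_survey(items, [("p1", 70.0, 1.0), ("p2", 70.0, 1.0)], [])


class TestDeriveCombined:
    def test_narrative_six_group_union(self, ranking_survey):
        """Enriched top-3 bread/yoghurt-desserts/soups plus the rich ranking
        walk (yoghurt-desserts first, spreads-cheese fourth) yields the
        six-group combined scenario."""
        alts = {g: f"a{k}" for k, g in enumerate(GROUPS6)}
        rich = _result_with_ranking(
            ranking_survey,
            "rich",
            [(g, alts[g]) for g in GROUPS6],
            {
                "yoghurt, cream desserts and pudding": 40.0,
                "potatoes, vegetables and legumes": 30.0,
                "non-alcoholic beverages and milk": 20.0,
                "savoury spreads, sweet spreads and cheese": 10.0,
                "bread": 1.0,
                "soups": 0.5,
            },
        )
        enriched = _result_with_ranking(
            ranking_survey,
            "enriched",
            [(g, alts[g]) for g in GROUPS6],
            {
                "bread": 50.0,
                "yoghurt, cream desserts and pudding": 45.0,
                "soups": 30.0,
                "potatoes, vegetables and legumes": 2.0,
                "non-alcoholic beverages and milk": 1.0,
                "savoury spreads, sweet spreads and cheese": 0.5,
            },
        )
        combined = ps.derive_combined_scenario(rich, enriched, k=3)
        assert set(combined.groups) == set(GROUPS6)
        assert len(combined.replacements) == 6
        # the first three carry the enriched scenario's alternatives
        assert combined.groups[:3] == [
            "bread", "yoghurt, cream desserts and pudding", "soups",
        ]

    def test_disjoint_topk_is_simple_union(self, ranking_survey):
        alts = {g: f"a{k}" for k, g in enumerate(GROUPS6)}
        rich = _result_with_ranking(
            ranking_survey, "rich",
            [(g, alts[g]) for g in GROUPS6[3:]],
            {GROUPS6[3]: 3.0, GROUPS6[4]: 2.0, GROUPS6[5]: 1.0},
        )
        enriched = _result_with_ranking(
            ranking_survey, "enriched",
            [(g, alts[g]) for g in GROUPS6[:3]],
            {GROUPS6[0]: 3.0, GROUPS6[1]: 2.0, GROUPS6[2]: 1.0},
        )
        combined = ps.derive_combined_scenario(rich, enriched, k=3)
        assert combined.groups == GROUPS6[:3] + GROUPS6[3:]

    def test_k1_with_identical_top_group(self, ranking_survey):
        alts = {g: f"a{k}" for k, g in enumerate(GROUPS6)}
        both = [(g, alts[g]) for g in GROUPS6[:2]]
        rich = _result_with_ranking(
            ranking_survey, "rich", both, {GROUPS6[0]: 5.0, GROUPS6[1]: 4.0}
        )
        enriched = _result_with_ranking(
            ranking_survey, "enriched", both, {GROUPS6[0]: 9.0, GROUPS6[1]: 1.0}
        )
        combined = ps.derive_combined_scenario(rich, enriched, k=1)
        assert combined.groups == [GROUPS6[0], GROUPS6[1]]

    def test_too_few_groups_is_error(self, ranking_survey):
        alts = {g: f"a{k}" for k, g in enumerate(GROUPS6)}
        one = [(GROUPS6[0], alts[GROUPS6[0]])]
        r = _result_with_ranking(ranking_survey, "rich", one, {GROUPS6[0]: 1.0})
        e = _result_with_ranking(ranking_survey, "enriched", one, {GROUPS6[0]: 2.0})
        with pytest.raises(ps.SurveyValidationError):
            ps.derive_combined_scenario(r, e, k=3)


# ---------------------------------------------------------------------------
# Nutrient summary table
# ---------------------------------------------------------------------------


class TestMeanNutrientIntakes:
    def _two_person_survey(self, w1, w2, kcal1, kcal2):
        item = ps.FoodItem("A", "A", "g", {"protein_g": 1.0, "energy_kcal": 100.0})
        return make_survey(
            [item],
            [("p1", 70.0, w1), ("p2", 70.0, w2)],
            [("p1", d, "A", kcal1) for d in (1, 2)]
            + [("p2", d, "A", kcal2) for d in (1, 2)],
        )

    def test_uniform_weights_mean(self):
        s = self._two_person_survey(1.0, 1.0, 1800.0, 2200.0)
        table = ps.mean_nutrient_intakes(s, ["energy_kcal"])
        assert table.loc["energy_kcal", "weighted_mean"] == pytest.approx(2000.0)

    def test_weighted_mean_1_3(self):
        # weights (1,3) on 2-day averages (100, 200) kcal -> 175
        s = self._two_person_survey(1.0, 3.0, 100.0, 200.0)
        table = ps.mean_nutrient_intakes(s, ["energy_kcal"])
        assert table.loc["energy_kcal", "weighted_mean"] == pytest.approx(175.0)

    def test_energy_neutral_substitution_leaves_energy_mean(self):
        items = [
            ps.FoodItem("lo", "lo", "g", {"protein_g": 1.0, "energy_kcal": 120.0}),
            ps.FoodItem("mid", "mid", "g", {"protein_g": 2.0, "energy_kcal": 250.0}),
            ps.FoodItem("hi", "hi", "g", {"protein_g": 30.0, "energy_kcal": 120.0}),
        ]
        s = make_survey(
            items, [("p1", 70.0, 1.0)],
            [("p1", 1, "lo", 300.0), ("p1", 2, "lo", 300.0)],
        )
        res = ps.apply_scenario(s, ps.ScenarioDefinition("s", (("g", "hi"),)))
        assert len(res.log) == 2
        before = ps.mean_nutrient_intakes(s, ["energy_kcal"])
        after = ps.mean_nutrient_intakes(res.modified_survey, ["energy_kcal"])
        assert after.loc["energy_kcal", "weighted_mean"] == before.loc[
            "energy_kcal", "weighted_mean"
        ]

    def test_missing_nutrient_errors(self, basic_survey):
        with pytest.raises(ps.SurveyValidationError):
            ps.mean_nutrient_intakes(basic_survey, ["selenium_ug"])
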