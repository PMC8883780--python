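import numpy as np
import pytest

from protsim import (
    ConsumptionRecord,
    FoodCompositionTable,
    FoodItem,
    Participant,
    ScenarioDefinition,
    Survey,
)


def make_item(code, group, protein, name=None, **nutrients):
    nut = {"protein_g": protein}
    nut.update(nutrients)
    return FoodItem(food_code=code, name=name or code, group=group, nutrients=nut)


def make_survey(items, participants, records):
    """Build a survey from ((code, group, protein), ...) item triples,
    ((pid, bw, weight), ...) participant triples and
    ((pid, day, code, grams), ...) record quadruples."""
    comp = FoodCompositionTable(
        [it if isinstance(it, FoodItem) else make_item(*it) for it in items]
    )
    parts = {
        pid: Participant(participant_id=pid, body_weight_kg=bw, analysis_weight=w)
        for pid, bw, w in participants
    }
    recs = [
        ConsumptionRecord(participant_id=p, day_index=d, food_code=c, grams=g)
        for p, d, c, g in records
    ]
    return Survey(participants=parts, records=recs, composition=comp)


@pytest.fixture
def basic_survey():
    """Three participants: one eligible, one at the boundary, one excluded."""
    items = [
        ("A1", "bread", 3.0),
        ("A2", "bread", 5.0),
        ("A3", "bread", 12.0),
        ("B1", "dairy", 2.0),
        ("B2", "dairy", 10.0),
    ]
    participants = [("p1", 80.0, 1.0), ("p2", 60.0, 2.0), ("p3", None, 1.0)]
    records = [
        ("p1", 1, "A1", 200.0),
        ("p1", 1, "B1", 150.0),
        ("p1", 2, "A1", 100.0),
        # p2: exactly 1.0 g/kg BW/d on both days (60 g protein, BW 60)
        ("p2", 1, "A3", 500.0),
        ("p2", 2, "A3", 500.0),
    ]
    return make_survey(items, participants, records)


def random_small_survey(rng: np.random.Generator):
    """Random survey: <= 10 participants, 2-3 groups, <= 5 foods per group.

    Protein contents are drawn from a small integer grid so ties (and
    items exactly at the P75) occur regularly.
    """
    groups = [f"grp{k}" for k in range(rng.integers(2, 4))]
    items = []
    for gi, group in enumerate(groups):
        n_foods = rng.integers(1, 6)
        for fi in range(n_foods):
            protein = float(rng.integers(0, 13))
            items.append((f"g{gi}f{fi}", group, protein))
    comp = FoodCompositionTable([make_item(*it) for it in items])

    n_part = int(rng.integers(2, 11))
    participants = []
    for pi in range(n_part):
        bw = None if rng.random() < 0.1 else float(rng.uniform(50, 95))
        participants.append((f"p{pi}", bw, float(rng.uniform(0.5, 2.0))))

    records = []
    codes = [it[0] for it in items]
    for pi in range(n_part):
        for day in (1, 2):
            for _ in range(rng.integers(0, 5)):
                records.append(
                    (
                        f"p{pi}",
                        day,
                        codes[rng.integers(len(codes))],
                        float(rng.uniform(0, 400)),
                    )
                )
    survey = make_survey(items, participants, records)

    # a scenario over every group that has an item strictly above its P75
    reps = []
    for group in groups:
        vals = sorted(it.protein_per_100g for it in comp.group_items(group))
        p75 = float(np.percentile(vals, 75))
        above = [
            it for it in comp.group_items(group) if it.protein_per_100g > p75
        ]
        if above:
            reps.append((group, above[0].food_code))
    scenario = (
        ScenarioDefinition("rand", tuple(reps), eligibility_cutoff=1.0)
        if reps
        else None
    )
    return survey, scenario
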