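import numpy as np
import pytest

from medlifenet.instrument import ResponseRecord, default_instrument


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


def adherent_answer(item) -> str:
    """An answer satisfying the item's adherence rule."""
    return "moderate" if item.coding == "tripartite" else item.adherent_levels[0]


def non_adherent_answer(item) -> str:
    """An answer violating the item's adherence rule."""
    if item.coding == "tripartite":
        return "high"
    return next(l for l in item.response_levels if l not in item.adherent_levels)


def make_record(instrument, answers, rid="r1", **demo) -> ResponseRecord:
    kwargs = dict(age=25.0, sex="female", bmi=22.0, smoking=False)
    kwargs.update(demo)
    return ResponseRecord(respondent_id=rid, item_answers=answers, **kwargs)


@pytest.fixture(scope="session")
def fully_adherent_record(instrument):
    return make_record(
        instrument, {it.item_id: adherent_answer(it) for it in instrument.items}
    )


@pytest.fixture(scope="session")
def fully_nonadherent_record(instrument):
    return make_record(
        instrument, {it.item_id: non_adherent_answer(it) for it in instrument.items}
    )


def random_record(instrument, rng: np.random.Generator, rid="r1") -> ResponseRecord:
    answers = {
        it.item_id: it.response_levels[rng.integers(len(it.response_levels))]
        for it in instrument.items
    }
    return make_record(instrument, answers, rid=rid)
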