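import numpy as np
import pandas as pd
import pytest

import indtasd as it


@pytest.fixture(scope="session")
def instrument():
    return it.default_instrument()


@pytest.fixture(scope="session")
def study_table():
    """The published validation 2x2: tool call vs expert DSM-5 diagnosis."""
    return it.ConfusionTable(tp=126, fp=8, fn=2, tn=89)


def make_child_answers(instrument, abnormal_ids, child_id="child"):
    """Concordant raw answers where exactly `abnormal_ids` are abnormal."""
    answers = []
    for q in instrument.questions:
        resp = q.abnormal_response if q.question_id in abnormal_ids else (
            "yes" if q.abnormal_response == "no" else "no")
        answers.append(it.RawAnswer(child_id, q.question_id, resp, resp))
    return answers


@pytest.fixture(scope="session")
def perfect_separation_params():
    """Noise-free cohort where class membership forces the tool call."""
    return it.default_params(
        seed=7, n=120,
        p_abnormal_pos={sd: 1.0 for sd in it.SUBDOMAIN_IDS},
        p_abnormal_neg={sd: 0.0 for sd in it.SUBDOMAIN_IDS},
        rater_disagreement=0.0, unsure_rate=0.0,
        b_item_rates_pos=(1.0, 1.0), b_item_rates_neg=(0.0, 0.0),
    )


def run_pipeline(cohort, instrument=None):
    """simulate -> score, returning the per-child report DataFrame."""
    instrument = instrument or it.default_instrument()
    return it.score_cohort(
        cohort.responses_frame(), cohort.section_b_frame(), instrument
    )
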