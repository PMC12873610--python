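"""Shared fixtures: tiny synthetic studies and an independent brute-force
consensus oracle used to cross-check the implementation."""

from __future__ import annotations

import pytest
from hypothesis import settings

from quorum.core import RaterAnswer, Status, TaskKind
from quorum.simulate import default_config, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def brute_force_decide(valid_values, threshold):
    """Reference decision: count occurrences of each distinct value with a
    plain scan; DECIDED iff exactly one value has count >= threshold.

    Independent of the package's tally path (no Counter, no dict of the
    implementation): returns (decided, value_or_None).
    """
    distinct = []
    for v in valid_values:
        if v not in distinct:
            distinct.append(v)
    winners = []
    for v in distinct:
        count = 0
        for u in valid_values:
            if u == v:
                count += 1
        if count >= threshold:
            winners.append(v)
    if len(winners) == 1:
        return True, winners[0]
    return False, None


def make_answers(item_id, task, entries):
    """Build RaterAnswer rows from (rater_id, status, value) tuples; a bare
    value means a VALID answer."""
    answers = []
    for k, entry in enumerate(entries):
        if isinstance(entry, tuple):
            rater_id, status, value = entry
        else:
            rater_id, status, value = f"r{k + 1}", Status.VALID, entry
        answers.append(
            RaterAnswer(item_id=item_id, rater_id=rater_id, task=task,
                        status=status, value=value)
        )
    return answers


@pytest.fixture(scope="session")
def categorical_study():
    """A small calibrated classification study (truth, responses, reviews)."""
    return simulate_study(default_config("categorical", seed=101, n_items=150))


@pytest.fixture(scope="session")
def extraction_study():
    """A small calibrated sample-size extraction study."""
    return simulate_study(default_config("extraction", seed=202, n_items=150))
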