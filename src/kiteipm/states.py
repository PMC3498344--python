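"""State and event alphabets of the multistate mark-recapture model.

A radio-tagged kite moves through a 16-state space combining six age
classes (alive birds), radio status (functioning transmitter or not),
cause of death (poison vs other) and an absorbing "unobserved dead"
state.  Age is deterministic given the release year because all birds
are tagged as nestlings, so age never needs to be inferred: it is baked
into the alive-state labels and the transition structure.

State layout (0-based indices used internally):

====  =========================================
 0-5  alive with functioning radio, ages juv..5my
 6-10 alive without functioning radio, ages 1y..5my
 11   recently dead by poison, radio functioning   (DP.t)
 12   recently dead by other cause, radio on       (DO.t)
 13   recently dead by poison, no radio            (DP.nt)
 14   recently dead by other cause, no radio       (DO.nt)
 15   unobserved dead (absorbing)
====  =========================================

Event codes follow the field coding 1-16: 1-6 seen alive with radio by
age; 7/8 recovered dead (poison/other) with radio; 9-13 seen alive
without radio by age (no juvenile code: tag loss cannot precede the
first birthday within the model year); 14/15 recovered dead without
radio; 16 neither seen nor heard.  Code 0 is a CSV filler for
pre-release years.
"""

from __future__ import annotations

AGE_CLASSES: tuple[str, ...] = ("juv", "1y", "2y", "3y", "4y", "5my")

N_STATES = 16
N_EVENTS = 16

# Alive-state indices
ALIVE_RADIO = {age: i for i, age in enumerate(AGE_CLASSES)}
ALIVE_NORADIO = {age: 6 + i for i, age in enumerate(AGE_CLASSES[1:])}
DP_T, DO_T, DP_NT, DO_NT, UNOBS_DEAD = 11, 12, 13, 14, 15

STATE_LABELS: tuple[str, ...] = (
    tuple(f"{a}.t" for a in AGE_CLASSES)
    + tuple(f"{a}.nt" for a in AGE_CLASSES[1:])
    + ("DP.t", "DO.t", "DP.nt", "DO.nt", "dead")
)

# Event code (1-based) -> unique compatible latent state, for codes 1-15.
EVENT_STATE: dict[int, int] = (
    {k + 1: ALIVE_RADIO[a] for k, a in enumerate(AGE_CLASSES)}
    | {7: DP_T, 8: DO_T}
    | {9 + k: ALIVE_NORADIO[a] for k, a in enumerate(AGE_CLASSES[1:])}
    | {14: DP_NT, 15: DO_NT}
)

EVENT_NOT_SEEN = 16


def age_successor(age: str) -> str:
    """Next age class after one year; the top class (5my) is absorbing."""
    i = AGE_CLASSES.index(age)
    return AGE_CLASSES[min(i + 1, len(AGE_CLASSES) - 1)]


def retention_class(age: str) -> int:
    """Radio-signal retention class k for a transition starting at ``age``.

    k=1 from tagging up to the end of the third year of life, k=2 between
    3 and 4 years old, k=3 thereafter.
    """
    i = AGE_CLASSES.index(age)
    if i <= 2:  # juv, 1y, 2y
        return 1
    if i == 3:  # 3y
        return 2
    return 3


def mortality_class(age: str) -> str:
    """Cause-of-death age class: juvenile, one year old, or 2+ (``2my``)."""
    i = AGE_CLASSES.index(age)
    if i == 0:
        return "juv"
    if i == 1:
        return "1y"
    return "2my"


def age_at_occasion(release_index: int, occasion_index: int) -> str:
    """Age class of a bird tagged as a nestling at ``release_index``."""
    if occasion_index < release_index:
        raise ValueError("occasion precedes release")
    return AGE_CLASSES[min(occasion_index - release_index, len(AGE_CLASSES) - 1)]


def _check_alphabets() -> None:
    assert len(AGE_CLASSES) == 6
    assert len(STATE_LABELS) == N_STATES == 6 + 5 + 4 + 1
    assert set(EVENT_STATE) == set(range(1, 16))
    # codes 1-15 map to distinct states; 16 is the only ambiguous code
    assert len(set(EVENT_STATE.values())) == 15
    assert UNOBS_DEAD not in EVENT_STATE.values()


_check_alphabets()
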