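"""Multistate capture-recapture likelihood for radio-tracked kites.

Transition and observation probabilities over the 16-state space, and
the exact (forward-algorithm) log-likelihood of annual encounter
histories.  Because age is encoded in the state labels, a single 16x16
transition matrix and a single 16x16 observation matrix serve every
individual and occasion; parameters differ by age only through the
state the bird occupies.

Dead birds carrying a functioning radio are assumed to be found with
probability one (radios are tracked monthly and corpses recovered soon
after death); reporting parameters apply only to the radio-less dead
states.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import states as st

__all__ = [
    "MsParams",
    "EncounterHistory",
    "transition_matrix",
    "observation_matrix",
    "ch_loglik",
]

_PROB_FIELDS = (
    "phi", "m_juv", "m_1y", "m_2my",
    "rho1", "rho2", "rho3",
    "p", "pA", "rP", "rO",
)


@dataclass(frozen=True)
class MsParams:
    """Parameters of the multistate model (all annual probabilities).

    phi
        survival, shared across ages and sexes.
    m_juv, m_1y, m_2my
        probability that a death was caused by poison, given death in
        the juvenile / one-year-old / two-plus age interval.
    rho1, rho2, rho3
        radio-signal retention by retention class (tagging to third
        birthday; third to fourth year; later years).
    p, pA
        encounter probability of a live bird with / without a
        functioning radio.
    rP, rO
        reporting probability of a radio-less bird dead by poison /
        by another cause.
    """

    phi: float
    m_juv: float
    m_1y: float
    m_2my: float
    rho1: float
    rho2: float
    rho3: float
    p: float
    pA: float
    rP: float
    rO: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def m(self, mort_class: str) -> float:
        return {"juv": self.m_juv, "1y": self.m_1y, "2my": self.m_2my}[mort_class]

    def rho(self, k: int) -> float:
        return (self.rho1, self.rho2, self.rho3)[k - 1]


@dataclass(frozen=True)
class EncounterHistory:
    """One tagged bird: annual event codes from release onwards.

    ``events`` is aligned to study occasions; entries before
    ``release_index`` are 0 (filler).  The event at the release occasion
    must be 1 (seen alive, radio on, juvenile) and is conditioned on,
    not modelled.
    """

    individual: str
    sex: str
    release_index: int
    events: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        ev = self.events
        if not 0 <= self.release_index < len(ev):
            raise ValueError("release index outside the event sequence")
        if any(e != 0 for e in ev[: self.release_index]):
            raise ValueError(f"{self.individual}: non-filler event before release")
        if ev[self.release_index] != 1:
            raise ValueError(
                f"{self.individual}: release event must be 1 (alive juvenile, "
                f"radio on), got {ev[self.release_index]}"
            )
        if any(not 1 <= e <= 16 for e in ev[self.release_index:]):
            raise ValueError(f"{self.individual}: event code outside 1..16")


def transition_matrix(params: MsParams) -> np.ndarray:
    """Annual 16x16 transition matrix over latent states.

    A live radio-carrying bird of age class a (retention class k,
    mortality class m_a) survives and keeps its signal with phi*rho_k,
    survives losing it with phi*(1-rho_k), or dies, the death being
    split by cause (m_a) and radio fate (rho_k).  Radio-less birds only
    redistribute over the no-radio states.  Recently-dead states pass
    to the absorbing unobserved-dead state.
    """
    T = np.zeros((st.N_STATES, st.N_STATES))
    phi = params.phi
    for age in st.AGE_CLASSES:
        nxt = st.age_successor(age)
        rho = params.rho(st.retention_class(age))
        m = params.m(st.mortality_class(age))
        i = st.ALIVE_RADIO[age]
        T[i, st.ALIVE_RADIO[nxt]] += phi * rho
        T[i, st.ALIVE_NORADIO[nxt]] += phi * (1.0 - rho)
        T[i, st.DP_T] += (1.0 - phi) * m * rho
        T[i, st.DP_NT] += (1.0 - phi) * m * (1.0 - rho)
        T[i, st.DO_T] += (1.0 - phi) * (1.0 - m) * rho
        T[i, st.DO_NT] += (1.0 - phi) * (1.0 - m) * (1.0 - rho)
        if age != "juv":
            j = st.ALIVE_NORADIO[age]
            T[j, st.ALIVE_NORADIO[nxt]] += phi
            T[j, st.DP_NT] += (1.0 - phi) * m
            T[j, st.DO_NT] += (1.0 - phi) * (1.0 - m)
    for dead in (st.DP_T, st.DO_T, st.DP_NT, st.DO_NT, st.UNOBS_DEAD):
        T[dead, st.UNOBS_DEAD] = 1.0
    return T


def observation_matrix(params: MsParams) -> np.ndarray:
    """16x16 event probabilities (rows: latent states, cols: codes 1-16)."""
    O = np.zeros((st.N_STATES, st.N_EVENTS))
    not_seen = st.EVENT_NOT_SEEN - 1
    for code, state in st.EVENT_STATE.items():
        if state in st.ALIVE_RADIO.values():
            pr = params.p
        elif state in st.ALIVE_NORADIO.values():
            pr = params.pA
        elif state == st.DP_T or state == st.DO_T:
            pr = 1.0
        elif state == st.DP_NT:
            pr = params.rP
        else:  # DO_NT
            pr = params.rO
        O[state, code - 1] = pr
        O[state, not_seen] += 1.0 - pr
    O[st.UNOBS_DEAD, not_seen] = 1.0
    return O


def _cohorts(histories):
    """Group histories by release occasion; returns {release: int array (n, L)}."""
    by_rel: dict[int, list[EncounterHistory]] = {}
    for h in histories:
        by_rel.setdefault(h.release_index, []).append(h)
    return {
        rel: np.array([h.events[rel:] for h in hs], dtype=np.intp)
        for rel, hs in sorted(by_rel.items())
    }


def ch_loglik(histories, params: MsParams, *, return_per_individual: bool = False):
    """Exact log-likelihood of encounter histories (males and females pooled).

    Forward recursion over the 16 latent states, conditioning on release
    in the alive-with-radio juvenile state.  An event sequence with zero
    probability under the model yields -inf and a diagnostic naming the
    first offending individual and occasion.
    """
    histories = list(histories)
    T = transition_matrix(params)
    O = observation_matrix(params)
    total = 0.0
    per_ind = {}
    for rel, events in _cohorts(histories).items():
        n, L = events.shape
        alpha = np.zeros((n, st.N_STATES))
        alpha[:, st.ALIVE_RADIO["juv"]] = 1.0  # condition on release event 1
        ll = np.zeros(n)
        for j in range(1, L):
            alpha = (alpha @ T) * O[:, events[:, j] - 1].T
            s = alpha.sum(axis=1)
            dead = s <= 0.0
            if dead.any():
                k = int(np.flatnonzero(dead)[0])
                who = [h for h in histories if h.release_index == rel][k]
                import warnings

                warnings.warn(
                    f"impossible event {events[k, j]} for individual "
                    f"{who.individual!r} at occasion {rel + j}",
                    stacklevel=2,
                )
                ll[dead] = -np.inf
                alpha[dead] = 0.0
                s = np.where(dead, 1.0, s)
            ll += np.log(s)
            alpha /= s[:, None]
        total += ll.sum()
        if return_per_individual:
            for h, v in zip(
                [h for h in histories if h.release_index == rel], ll
            ):
                per_ind[h.individual] = float(v)
    if return_per_individual:
        return float(total), per_ind
    return float(total)
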