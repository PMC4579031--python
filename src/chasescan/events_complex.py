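"""Complex gaze events: pursuit and exploration, and saccade labeling.

Pursuit starts either with an FSM or with two consecutive SSMs (separated
by a saccade) that focus the same agents, continues as long as the agent
sets of consecutive basic events overlap, and must contain at least one
FSM.  Everything else (fixations and SSMs) is exploration.  Saccades are
assigned to the segment that follows them: a saccade followed by
exploration is an exploration saccade (ES); a saccade followed by a
pursuit-member event is a catch-up saccade, ordered within its pursuit
(CS1, CS2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chasescan.events_basic import BasicEvent

__all__ = ["ComplexEvent", "SaccadeLabel", "extract_complex",
           "label_saccades", "compare_streams", "rasterize_saccade_labels"]

SMOOTH_KINDS = ("fixation", "SSM", "FSM")


@dataclass
class ComplexEvent:
    kind: str                     # pursuit | exploration
    t_start: float
    t_end: float
    member_basic_events: list    # time-ordered BasicEvents incl. saccades
    agent_set: frozenset

    @property
    def start(self) -> int:
        return self.member_basic_events[0].start

    @property
    def end(self) -> int:
        return self.member_basic_events[-1].end


@dataclass
class SaccadeLabel:
    saccade: BasicEvent
    label: str | None             # "ES", "CS" or None (trailing, unlabeled)
    cs_order: int | None = None   # 1-based order within its pursuit


def _overlap(a: BasicEvent, b: BasicEvent) -> bool:
    return bool(a.focused_agents & b.focused_agents)


def extract_complex(basics: list[BasicEvent],
                    max_link_gap_s: float = 0.25) -> list[ComplexEvent]:
    """Aggregate time-ordered basic events into pursuit and exploration.

    ``max_link_gap_s`` bounds the uncoded time allowed between two smooth
    events for the agent-set continuation rule to link them; longer
    uncoded stretches break the chain.
    """
    evs = sorted(basics, key=lambda e: e.start)
    n = len(evs)
    sm = [k for k, e in enumerate(evs) if e.kind in SMOOTH_KINDS]

    def linked(j):  # link between smooth events sm[j] and sm[j+1]
        a, b = evs[sm[j]], evs[sm[j + 1]]
        covered = sum(evs[k].duration for k in range(sm[j] + 1, sm[j + 1])
                      if evs[k].kind == "saccade")
        gap = (b.t_start - a.t_end) - covered
        return _overlap(a, b) and gap <= max_link_gap_s

    def has_saccade_between(j):
        return any(evs[k].kind == "saccade" for k in range(sm[j] + 1, sm[j + 1]))

    pursuit_of = [None] * n  # pursuit id per event index
    pid = 0
    j = 0
    while j < len(sm):
        e = evs[sm[j]]
        starts = False
        if e.kind == "FSM":
            starts = True
        elif (e.kind == "SSM" and j + 1 < len(sm)
              and evs[sm[j + 1]].kind == "SSM" and has_saccade_between(j)
              and linked(j)):
            starts = True
        if not starts:
            j += 1
            continue
        j1 = j
        while j1 + 1 < len(sm) and linked(j1):
            j1 += 1
        if any(evs[sm[k]].kind == "FSM" for k in range(j, j1 + 1)):
            for k in range(sm[j], sm[j1] + 1):
                pursuit_of[k] = pid
            # the saccade immediately preceding the pursuit joins it (CS1)
            k = sm[j] - 1
            if k >= 0 and evs[k].kind == "saccade" and pursuit_of[k] is None:
                pursuit_of[k] = pid
            pid += 1
            j = j1 + 1
        else:
            j += 1

    complexes: list[ComplexEvent] = []

    def emit(kind, members):
        agents = frozenset().union(*(e.focused_agents for e in members))
        complexes.append(ComplexEvent(kind, members[0].t_start,
                                      members[-1].t_end, members, agents))

    # pursuit segments
    k = 0
    while k < n:
        if pursuit_of[k] is not None:
            pid_k = pursuit_of[k]
            members = []
            while k < n and pursuit_of[k] == pid_k:
                members.append(evs[k])
                k += 1
            emit("pursuit", members)
        else:
            k += 1
    # exploration: contiguous stretches of unassigned events containing
    # at least one smooth event (pure-saccade leftovers stay unassigned)
    k = 0
    while k < n:
        if pursuit_of[k] is None:
            members = []
            while k < n and pursuit_of[k] is None:
                members.append(evs[k])
                k += 1
            if any(e.kind in SMOOTH_KINDS for e in members):
                emit("exploration", members)
        else:
            k += 1
    complexes.sort(key=lambda c: c.t_start)
    return complexes


def label_saccades(basics: list[BasicEvent],
                   complexes: list[ComplexEvent]) -> list[SaccadeLabel]:
    """Label saccades ES/CS by the segment of the event that follows them."""
    evs = sorted(basics, key=lambda e: e.start)
    owner = {}
    for c in complexes:
        for e in c.member_basic_events:
            owner[id(e)] = c
    labels = []
    cs_count: dict[int, int] = {}
    for i, e in enumerate(evs):
        if e.kind != "saccade":
            continue
        nxt = next((f for f in evs[i + 1:] if f.kind in SMOOTH_KINDS), None)
        if nxt is None or id(nxt) not in owner:
            labels.append(SaccadeLabel(e, None))
            continue
        c = owner[id(nxt)]
        if c.kind == "pursuit":
            cid = id(c)
            cs_count[cid] = cs_count.get(cid, 0) + 1
            labels.append(SaccadeLabel(e, "CS", cs_count[cid]))
        else:
            labels.append(SaccadeLabel(e, "ES"))
    return labels


def rasterize_saccade_labels(labels: list[SaccadeLabel], n_frames: int,
                             cs1_only: bool = False) -> np.ndarray:
    """Per-frame label array ('ES'/'CS'/'CS1'/'' ) at the display rate."""
    out = np.full(n_frames, "", dtype=object)
    for lab in labels:
        if lab.label is None:
            continue
        name = lab.label
        if lab.label == "CS" and cs1_only:
            name = "CS1" if lab.cs_order == 1 else "CS"
        out[lab.saccade.start:lab.saccade.end] = name
    return out


def compare_streams(a: np.ndarray, b: np.ndarray,
                    positive_class: str, negative_class: str) -> dict:
    """Frame-wise agreement of two labeled streams on a two-class contrast.

    Confusion counts accumulate over the frames where either stream
    asserts one of the two classes; within those frames any label other
    than the positive class counts as negative.  ``b`` is the reference
    for sensitivity/specificity.  Returns accuracy, sensitivity,
    specificity and the Matthews correlation coefficient.
    """
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("streams must cover the same time base")
    sel = np.isin(a, [positive_class, negative_class]) | \
        np.isin(b, [positive_class, negative_class])
    if not sel.any():
        raise ValueError("no frames assert either class; metrics undefined")
    ap = a[sel] == positive_class
    bp = b[sel] == positive_class
    tp = int(np.sum(ap & bp))
    tn = int(np.sum(~ap & ~bp))
    fp = int(np.sum(ap & ~bp))
    fn = int(np.sum(~ap & bp))
    n = tp + tn + fp + fn
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "mcc": float(mcc),
        "confusion": (tp, fp, fn, tn),
    }
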