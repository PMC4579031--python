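import numpy as np
import pytest

from chasescan.events_basic import BasicEvent
from chasescan.events_complex import (compare_streams, extract_complex,
                                      label_saccades)

FR = 85.0


def _ev(kind, start, end, agents=()):
    return BasicEvent(kind, start, end, start / FR, end / FR,
                      frozenset(agents))


def _seq(*specs):
    """Build a contiguous event sequence from (kind, n_frames, agents)."""
    events, f = [], 0
    for kind, n, *rest in specs:
        agents = rest[0] if rest else ()
        events.append(_ev(kind, f, f + n, agents))
        f += n
    return events


class TestExtractComplex:
    def test_fixation_saccade_fixation_is_exploration(self):
        evs = _seq(("fixation", 30), ("saccade", 3), ("fixation", 30))
        cx = extract_complex(evs)
        assert [c.kind for c in cx] == ["exploration"]
        labels = label_saccades(evs, cx)
        assert [l.label for l in labels] == ["ES"]

    def test_chained_pursuit_with_cs_orders(self):
        evs = _seq(("saccade", 3), ("FSM", 20, {3}), ("saccade", 3),
                   ("SSM", 20, {3, 4}), ("saccade", 3), ("FSM", 20, {4}))
        cx = extract_complex(evs)
        assert [c.kind for c in cx] == ["pursuit"]
        assert cx[0].agent_set == {3, 4}
        labels = label_saccades(evs, cx)
        assert [(l.label, l.cs_order) for l in labels] == \
            [("CS", 1), ("CS", 2), ("CS", 3)]

    def test_disjoint_ssms_without_fsm_are_exploration(self):
        evs = _seq(("SSM", 20, {1}), ("saccade", 3), ("SSM", 20, {2}))
        cx = extract_complex(evs)
        assert all(c.kind == "exploration" for c in cx)

    def test_ssm_pair_start_rule(self):
        # two consecutive same-agent SSMs separated by a saccade start a
        # pursuit retroactively, provided an FSM occurs in the chain
        evs = _seq(("SSM", 20, {2}), ("saccade", 3), ("SSM", 20, {2}),
                   ("saccade", 3), ("FSM", 20, {2}))
        cx = extract_complex(evs)
        assert [c.kind for c in cx] == ["pursuit"]
        assert cx[0].member_basic_events[0].kind == "SSM"

    def test_no_fsm_no_pursuit(self, events_group_clean):
        stripped = [e for e in events_group_clean if e.kind != "FSM"]
        cx = extract_complex(stripped)
        assert all(c.kind == "exploration" for c in cx)

    def test_partition_no_frame_in_two_complexes(self, events_group_clean):
        cx = extract_complex(events_group_clean)
        covered = np.zeros(100000, dtype=int)
        for c in cx:
            covered[c.start:c.end] += 1
        assert covered.max() <= 1

    def test_every_pursuit_contains_fsm(self, events_group_clean):
        for c in extract_complex(events_group_clean):
            if c.kind == "pursuit":
                assert any(e.kind == "FSM" for e in c.member_basic_events)


class TestLabelSaccades:
    def test_cs_orders_reset_per_pursuit(self):
        evs = _seq(("saccade", 3), ("FSM", 20, {1}),
                   ("fixation", 30, ()),       # breaks the chain (no overlap)
                   ("saccade", 3), ("FSM", 20, {2}))
        cx = extract_complex(evs)
        pursuits = [c for c in cx if c.kind == "pursuit"]
        assert len(pursuits) == 2
        labels = [l for l in label_saccades(evs, cx) if l.label == "CS"]
        assert [l.cs_order for l in labels] == [1, 1]

    def test_trailing_saccade_unlabeled(self):
        evs = _seq(("fixation", 30), ("saccade", 3))
        cx = extract_complex(evs)
        labels = label_saccades(evs, cx)
        assert labels[-1].label is None


class TestCompareStreams:
    def test_identical_streams(self):
        a = np.array(["ES", "ES", "CS", "", "CS"], dtype=object)
        out = compare_streams(a, a.copy(), "CS", "ES")
        assert out["accuracy"] == 1.0 and out["mcc"] == pytest.approx(1.0)

    def test_complementary_streams(self):
        a = np.array(["ES", "CS"] * 10, dtype=object)
        b = np.array(["CS", "ES"] * 10, dtype=object)
        assert compare_streams(a, b, "CS", "ES")["mcc"] == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.choice(["CS", "ES"], size=300).astype(object)
            b = rng.choice(["CS", "ES"], size=300).astype(object)
            out = compare_streams(a, b, "CS", "ES")
            tp = np.sum((a == "CS") & (b == "CS"))
            tn = np.sum((a == "ES") & (b == "ES"))
            fp = np.sum((a == "CS") & (b == "ES"))
            fn = np.sum((a == "ES") & (b == "CS"))
            assert out["accuracy"] == pytest.approx((tp + tn) / 300)
            assert out["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert out["specificity"] == pytest.approx(tn / (tn + fp))
            mcc = (tp * tn - fp * fn) / np.sqrt(
                float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            assert out["mcc"] == pytest.approx(mcc)

    def test_class_swap_swaps_sensitivity_specificity(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["CS", "ES"], size=500).astype(object)
        b = rng.choice(["CS", "ES"], size=500).astype(object)
        fwd = compare_streams(a, b, "CS", "ES")
        rev = compare_streams(a, b, "ES", "CS")
        assert fwd["sensitivity"] == pytest.approx(rev["specificity"])
        assert fwd["specificity"] == pytest.approx(rev["sensitivity"])
        assert fwd["accuracy"] == pytest.approx(rev["accuracy"])
        assert fwd["mcc"] == pytest.approx(rev["mcc"])

    def test_empty_comparison_raises(self):
        a = np.array(["", ""], dtype=object)
        with pytest.raises(ValueError):
            compare_streams(a, a, "CS", "ES")
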