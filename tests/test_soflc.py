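"""Self-organizing layer: decomposition, performance-index lookup, rule
modification with credit assignment, firing statistics and extraction."""

from itertools import combinations

import pytest

from t2soflc.fuzzy_core.rules import Rule, RuleBase
from t2soflc.fuzzy_core.sets import INPUT_LABELS, build_partition
from t2soflc.soflc import (
    PAIRS,
    ControllerInputs,
    FiringStats,
    PerformanceIndexMatrix,
    RuleHistoryBuffer,
    SelfOrganizingController,
    StepRecord,
    decompose,
    extract_rules,
    firing_percentages,
    label_inputs,
    label_offset,
    offset_to_correction,
    pi_lookup,
    record_firing,
    so_update,
)


class TestDecompose:
    def test_six_ordered_pairs(self):
        out = decompose(ControllerInputs(0.1, 0.2, 0.3, 0.4))
        assert [pair for pair, _ in out] == list(PAIRS)
        assert out[0][1] == (0.1, 0.2)
        assert out[5][1] == (0.3, 0.4)

    def test_no_repeated_variable_within_pair(self):
        assert all(a != b for a, b in PAIRS)

    def test_matches_combination_enumeration(self):
        assert set(PAIRS) == set(combinations(("E_MR", "IE_MR", "E_BP", "IE_BP"), 2))


class TestPerformanceIndex:
    def test_printed_cells(self):
        pi = PerformanceIndexMatrix.from_csv()
        assert pi_lookup(pi, "ZE", "ZE") == "ZE"
        assert pi_lookup(pi, "NB", "NB") == "NB"
        assert pi_lookup(pi, "NS", "PS") == "ZE"

    def test_monotonicity_enforced_at_load(self):
        pi = PerformanceIndexMatrix.from_csv()
        order = {lab: i for i, lab in enumerate(INPUT_LABELS)}
        for e in INPUT_LABELS:
            row = [order[pi.lookup(e, ie)] for ie in INPUT_LABELS]
            assert row == sorted(row)
        for ie in INPUT_LABELS:
            col = [order[pi.lookup(e, ie)] for e in INPUT_LABELS]
            assert col == sorted(col)

    def test_non_monotone_table_rejected(self):
        pi = PerformanceIndexMatrix.from_csv()
        table = dict(pi.table)
        table[("ZE", "PB")] = "NB"
        with pytest.raises(ValueError):
            PerformanceIndexMatrix(table)

    def test_unknown_label_rejected(self):
        pi = PerformanceIndexMatrix.from_csv()
        with pytest.raises(KeyError):
            pi.lookup("??", "ZE")

    def test_offset_round_trip(self):
        for lab in INPUT_LABELS:
            assert offset_to_correction(label_offset(lab)) == lab
        assert offset_to_correction(9) == "PB" and offset_to_correction(-9) == "NB"


class TestLabelInputs:
    var = build_partition((-1.0, 1.0), INPUT_LABELS)

    def test_peak_hits_label(self):
        assert label_inputs(0.0, self.var) == "ZE"
        assert label_inputs(1.0, self.var) == "PB"
        assert label_inputs(-1.0, self.var) == "NB"

    def test_out_of_universe_clamped(self):
        assert label_inputs(5.0, self.var) == "PB"

    def test_tie_resolves_toward_ze(self):
        # midpoint between the PS and PM peaks
        assert label_inputs(0.5, self.var) == "PS"
        assert label_inputs(-0.5, self.var) == "NS"


def _record(max_sig=None, labels=None):
    labels = labels or {"E_MR": "NS", "IE_MR": "ZE", "E_BP": "ZE", "IE_BP": "ZE"}
    max_rule = {pair: None for pair in PAIRS}
    if max_sig is not None:
        max_rule[(max_sig[0], max_sig[2])] = max_sig
    return StepRecord(labels=labels, max_rule=max_rule, direction=1)


class TestSoUpdate:
    def test_ze_correction_is_fixed_point(self):
        rb = RuleBase("atracurium", [Rule.make(("E_MR", "NS"), ("IE_MR", "NS"), "PS")])
        before = rb.copy()
        changes = so_update(rb, _record(("E_MR", "NS", "IE_MR", "NS")), "ZE")
        assert changes == [] and rb == before

    def test_shift_saturates_at_pb(self):
        sig = ("E_MR", "NS", "IE_MR", "NS")
        rb = RuleBase("atracurium", [Rule.make(sig[:2], sig[2:], "PB")])
        so_update(rb, _record(sig), "PB")
        assert rb.get(sig).consequent == "PB"

    def test_shift_by_signed_offset(self):
        sig = ("E_MR", "NS", "IE_MR", "NS")
        rb = RuleBase("atracurium", [Rule.make(sig[:2], sig[2:], "PM")])
        so_update(rb, _record(sig), "NM")
        assert rb.get(sig).consequent == "ZE"

    def test_missing_signature_generates_rule(self):
        rb = RuleBase("atracurium")
        changes = so_update(rb, _record(), "PM")
        # one new rule per decomposed subsystem, consequent = ZE + offset
        assert len(changes) == len(PAIRS)
        assert all(action == "add" and new == "PM" for action, _, _, new in changes)

    def test_negative_offset_on_missing_rule_saturates_at_ze(self):
        rb = RuleBase("atracurium")
        so_update(rb, _record(), "NB")
        assert all(r.consequent == "ZE" for r in rb.rules())

    def test_never_duplicates_signatures(self):
        rb = RuleBase("atracurium")
        for corr in ("PM", "PB", "NS", "PS"):
            so_update(rb, _record(), corr)
        sigs = [r.signature for r in rb.rules()]
        assert len(sigs) == len(set(sigs)) == len(PAIRS)


class TestHistoryBuffer:
    def test_returns_record_after_delay(self):
        buf = RuleHistoryBuffer(delay_steps=3)
        recs = [_record() for _ in range(6)]
        out = [buf.push(r) for r in recs]
        assert out[:3] == [None, None, None]
        assert out[3] is recs[0] and out[5] is recs[2]

    def test_zero_delay_immediate(self):
        buf = RuleHistoryBuffer(0)
        r = _record()
        assert buf.push(r) is r


class TestFiringStats:
    def test_percentage_arithmetic(self):
        stats = FiringStats()
        sigs = [("E_MR", "NS", "E_BP", "NS"), ("E_MR", "ZE", "E_BP", "ZE"),
                ("E_MR", "PS", "E_BP", "PS")]
        fires = {sigs[0]: 5, sigs[1]: 3, sigs[2]: 2}
        for i in range(100):
            fired = [s for s, n in fires.items() if i < n]
            record_firing(stats, fired)
        pct = firing_percentages(stats)
        assert pct[sigs[0]] == 5.0 and pct[sigs[1]] == 3.0 and pct[sigs[2]] == 2.0

    def test_always_fired_is_100(self):
        stats = FiringStats()
        sig = ("E_MR", "ZE", "IE_MR", "ZE")
        for _ in range(7):
            stats.record([sig])
        assert stats.percentage(sig) == 100.0

    def test_never_fired_is_0(self):
        stats = FiringStats()
        stats.record([])
        assert stats.percentage(("E_MR", "ZE", "IE_MR", "ZE")) == 0.0

    def test_empty_stats_raise(self):
        with pytest.raises(ZeroDivisionError):
            FiringStats().percentages()


class TestExtractRules:
    def _base_and_stats(self):
        rules = [
            Rule.make(("E_MR", "NS"), ("IE_MR", "NS"), "PS"),
            Rule.make(("E_MR", "ZE"), ("IE_MR", "ZE"), "ZE"),
            Rule.make(("E_MR", "PS"), ("IE_MR", "PS"), "PM"),
        ]
        rb = RuleBase("atracurium", rules)
        stats = FiringStats()
        fires = {rules[0].signature: 12, rules[1].signature: 9, rules[2].signature: 50}
        for i in range(1000):
            stats.record([s for s, n in fires.items() if i < n])
        return rb, stats  # 1.2%, 0.9%, 5.0%

    def test_threshold_zero_keeps_everything(self):
        rb, stats = self._base_and_stats()
        assert len(extract_rules(rb, stats, 0.0)) == len(rb)

    def test_one_percent_threshold_drops_trivial(self):
        rb, stats = self._base_and_stats()
        reduced = extract_rules(rb, stats, 1.0)
        assert len(reduced) == 2
        assert ("E_MR", "ZE", "IE_MR", "ZE") not in reduced

    def test_empty_result_warns(self):
        rb, stats = self._base_and_stats()
        with pytest.warns(UserWarning):
            extract_rules(rb, stats, 99.0)


class TestControllerBasics:
    def test_unknown_kind_rejected(self, expert_atr, expert_iso):
        with pytest.raises(ValueError):
            SelfOrganizingController("type3", expert_atr, expert_iso)

    def test_outputs_clamped_nonnegative(self, expert_atr, expert_iso):
        c = SelfOrganizingController("type1", expert_atr.copy(), expert_iso.copy())
        for _ in range(50):
            u1, u2 = c.step(1.0, 60.0, 0.8, 100.0)  # strongly over-drugged state
            assert u1 >= 0.0 and u2 >= 0.0

    def test_firing_stats_accumulate(self, expert_atr, expert_iso):
        c = SelfOrganizingController("type1", expert_atr.copy(), expert_iso.copy())
        for _ in range(10):
            c.step(0.7, 110.0, 0.8, 100.0)
        assert c.stats["atracurium"].total == 10 * len(PAIRS)
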