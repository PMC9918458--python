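"""Differential statistics, trend classification, sFC and signature cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_stepup, hypergeom_upper_tail
from trendsig import trend_signatures as tsg
from trendsig.errors import ValidationError


def _expr(groups: dict):
    """Matrix + sheet from {class: {probe: values}}."""
    classes = list(groups)
    probes = list(groups[classes[0]])
    cols, tissues = [], []
    data = {p: [] for p in probes}
    for cls in classes:
        n = len(next(iter(groups[cls].values())))
        for i in range(n):
            cols.append(f"{cls}{i}")
            tissues.append(cls)
            for p in probes:
                data[p].append(groups[cls][p][i])
    m = pd.DataFrame([data[p] for p in probes], index=probes, columns=cols)
    sheet = pd.DataFrame({"sample_id": cols, "tissue": tissues, "study": "s1"})
    return m, sheet


class TestDifferentialProbes:
    def test_pooled_t_hand_example(self):
        m, sheet = _expr({"ATC": {"p1": [1, 2, 3]}, "DTC": {"p1": [3, 4, 5]}})
        res = tsg.differential_probes(m, sheet, "ATC", "DTC")
        assert res.loc["p1", "log2fc"] == pytest.approx(-2.0)
        assert res.loc["p1", "t_stat"] == pytest.approx(-2.449489742783178)
        assert res.loc["p1", "p"] == pytest.approx(0.07048399691021993, rel=1e-9)

    def test_equal_means_equal_spread(self):
        m, sheet = _expr({"ATC": {"p1": [1, 2, 3]}, "DTC": {"p1": [3, 2, 1]}})
        res = tsg.differential_probes(m, sheet, "ATC", "DTC")
        assert res.loc["p1", "t_stat"] == 0.0
        assert res.loc["p1", "p"] == 1.0

    def test_degenerate_constant_probe_flagged(self):
        m, sheet = _expr({"ATC": {"p1": [2, 2, 2]}, "DTC": {"p1": [2, 2, 2]}})
        res = tsg.differential_probes(m, sheet, "ATC", "DTC")
        assert bool(res.loc["p1", "degenerate"])
        assert res.loc["p1", "p"] == 1.0 and res.loc["p1", "t_stat"] == 0.0

    def test_small_class_rejected(self):
        m, sheet = _expr({"ATC": {"p1": [1.0]}, "DTC": {"p1": [1, 2, 3]}})
        with pytest.raises(ValidationError):
            tsg.differential_probes(m, sheet, "ATC", "DTC")

    def test_bh_matches_stepup_oracle(self):
        rng = np.random.default_rng(0)
        m, sheet = _expr({
            "ATC": {f"p{i}": rng.normal(i * 0.1, 1, 5).tolist()
                    for i in range(40)},
            "DTC": {f"p{i}": rng.normal(0, 1, 5).tolist() for i in range(40)},
        })
        res = tsg.differential_probes(m, sheet, "ATC", "DTC")
        np.testing.assert_allclose(res["q"], bh_stepup(res["p"]), atol=1e-12)
        # step-up hand case embedded in the oracle itself
        np.testing.assert_allclose(
            bh_stepup([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def _cmp(frames: dict):
    """Build a comparison table with given log2fc/q per probe."""
    idx = pd.Index(list(frames), name="probe_id")
    return pd.DataFrame({
        "log2fc": [frames[p][0] for p in idx],
        "q": [frames[p][1] for p in idx],
    }, index=idx)


class TestClassifyTrends:
    pm = pd.DataFrame({"probe_id": ["a1", "a2", "b1"],
                       "gene_id": ["GA", "GA", "GB"]})

    def test_single_probe_trend_up(self):
        r1 = _cmp({"a1": (1.0, 0.01), "a2": (0.5, 0.5), "b1": (1.0, 0.01)})
        r2 = _cmp({"a1": (1.0, 0.01), "a2": (0.5, 0.5), "b1": (1.0, 0.01)})
        r3 = _cmp({"a1": (2.0, 0.01), "a2": (0.5, 0.5), "b1": (2.0, 0.01)})
        out = tsg.classify_trends(r1, r2, r3, self.pm)
        assert out.loc["GA", "label"] == "TrendUp"
        assert out.loc["GA", "representative_probe"] == "a1"

    def test_discordant_probes_excluded(self):
        r1 = _cmp({"a1": (1.0, 0.01), "a2": (-1.0, 0.01), "b1": (0.1, 0.9)})
        r2 = _cmp({"a1": (1.0, 0.01), "a2": (-1.0, 0.01), "b1": (0.1, 0.9)})
        r3 = _cmp({"a1": (2.0, 0.01), "a2": (-2.0, 0.01), "b1": (0.1, 0.9)})
        out = tsg.classify_trends(r1, r2, r3, self.pm)
        assert out.loc["GA", "label"] == "excluded_discordant"

    def test_two_of_three_significant_is_not_deg(self):
        r1 = _cmp({"a1": (1.0, 0.01), "a2": (1, 1), "b1": (1, 1)})
        r2 = _cmp({"a1": (1.0, 0.01), "a2": (1, 1), "b1": (1, 1)})
        r3 = _cmp({"a1": (2.0, 0.30), "a2": (1, 1), "b1": (1, 1)})
        out = tsg.classify_trends(r1, r2, r3, self.pm)
        assert out.loc["GA", "label"] == "not_deg"

    def test_nonmonotone_significant_probe_has_no_trend(self):
        r1 = _cmp({"a1": (1.0, 0.01), "a2": (1, 1), "b1": (1, 1)})
        r2 = _cmp({"a1": (-1.0, 0.01), "a2": (1, 1), "b1": (1, 1)})
        r3 = _cmp({"a1": (0.5, 0.01), "a2": (1, 1), "b1": (1, 1)})
        out = tsg.classify_trends(r1, r2, r3, self.pm)
        assert out.loc["GA", "label"] == "not_deg"

    def test_representative_probe_smallest_q2(self):
        r1 = _cmp({"a1": (1.0, 0.01), "a2": (2.0, 0.01), "b1": (1, 1)})
        r2 = _cmp({"a1": (1.0, 0.02), "a2": (2.0, 0.01), "b1": (1, 1)})
        r3 = _cmp({"a1": (2.0, 0.01), "a2": (4.0, 0.01), "b1": (1, 1)})
        out = tsg.classify_trends(r1, r2, r3, self.pm)
        assert out.loc["GA", "representative_probe"] == "a2"
        assert out.loc["GA", "fc_step1"] == 2.0

    def test_unmapped_probe_rejected(self):
        r = _cmp({"zz": (1.0, 0.01)})
        with pytest.raises(ValidationError):
            tsg.classify_trends(r, r, r, self.pm)


class TestStandardizeFC:
    def test_hand_example(self):
        out = tsg.standardize_fc(pd.Series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1, 0, 1])

    def test_location_invariance(self):
        x = pd.Series([0.3, -1.2, 2.0, 0.7])
        np.testing.assert_allclose(tsg.standardize_fc(x),
                                   tsg.standardize_fc(x + 10), atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_postcondition(self, seed):
        x = pd.Series(np.random.default_rng(seed).normal(size=50))
        out = tsg.standardize_fc(x)
        assert abs(out.mean()) < 1e-9 and abs(out.std(ddof=1) - 1) < 1e-9

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            tsg.standardize_fc(pd.Series([1.0, 1.0, 1.0]))


def _trend(labels: dict):
    return pd.DataFrame({
        "label": list(labels.values()),
        "representative_probe": "x", "fc_step1": 0.0, "fc_step2": 0.0,
    }, index=pd.Index(labels, name="gene_id"))


class TestAssignSignatures:
    def _assign(self, cases):
        """cases: gene -> (label, s1, s2)."""
        table = _trend({g: v[0] for g, v in cases.items()})
        s1 = pd.Series({g: v[1] for g, v in cases.items()})
        s2 = pd.Series({g: v[2] for g, v in cases.items()})
        return tsg.assign_signatures(table, s1, s2)

    @pytest.mark.parametrize("label,s1,s2,expected", [
        ("TrendUp", 4.5, 1.5, "S1"),
        ("TrendUp", 1.5, 4.5, "S2"),
        ("TrendUp", 2.5, 2.5, "S3"),
        ("TrendUp", 5.0, 2.5, "S3"),      # strong step1 but step2 not < lo
        ("TrendUp", 1.0, 1.0, "unassigned"),
        ("TrendUp", 4.0, 1.5, "unassigned"),  # boundary is strict
        ("TrendDown", -4.5, -1.0, "S1"),
        ("TrendDown", -1.0, -4.5, "S2"),
        ("TrendDown", -2.5, -2.5, "S3"),
        ("TrendDown", -1.5, -1.5, "unassigned"),
    ])
    def test_printed_cutoffs(self, label, s1, s2, expected):
        out = self._assign({"G": (label, s1, s2)})
        assert out.loc["G", "signature"] == expected

    def test_precedence_keeps_signatures_disjoint(self):
        out = self._assign({"G": ("TrendUp", 4.5, 1.5)})
        assert out.loc["G", "signature"] == "S1"  # also satisfies nothing else

    def test_gene_order_invariance(self):
        cases = {"G3": ("TrendUp", 2.5, 2.5), "G1": ("TrendUp", 4.5, 1.5),
                 "G2": ("TrendDown", -1.0, -4.5)}
        a = self._assign(cases)
        b = self._assign(dict(reversed(list(cases.items()))))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_sfc_rejected(self):
        table = _trend({"G": "TrendUp"})
        with pytest.raises(ValidationError):
            tsg.assign_signatures(table, pd.Series(dtype=float),
                                  pd.Series(dtype=float))


class TestEnrichment:
    def test_perfect_overlap_extreme_p(self):
        universe = [f"g{i}" for i in range(100)]
        ann = {"setA": universe[:5]}
        out = tsg.enrichment_test(universe[:5], ann, universe)
        assert out.loc[0, "overlap"] == 5
        assert out.loc[0, "p"] == pytest.approx(
            hypergeom_upper_tail(5, 100, 5, 5), rel=1e-9)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = tsg.enrichment_test(universe[:5], {"s": universe[10:15]},
                                  universe)
        assert out.loc[0, "overlap"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(18)]
        for _ in range(20):
            gene_set = list(rng.choice(universe, size=6, replace=False))
            ann = {"s": list(rng.choice(universe, size=7, replace=False))}
            out = tsg.enrichment_test(gene_set, ann, universe)
            k = len(set(gene_set) & set(ann["s"]))
            assert out.loc[0, "p"] == pytest.approx(
                hypergeom_upper_tail(k, 18, 7, 6), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            tsg.enrichment_test([], {}, [])


def test_trend_lists_disjoint_and_signatures_partition():
    from conftest import small_expr_config
    from trendsig.synthdata import gen_multistudy_expression
    from trendsig.trend_signatures import derive_signatures
    m, sheet, pm, _ = gen_multistudy_expression(small_expr_config(seed=13))
    res = derive_signatures(m, sheet, pm)
    tt, sig = res["trend_table"], res["signatures"]
    up = set(tt.index[tt["label"] == "TrendUp"])
    down = set(tt.index[tt["label"] == "TrendDown"])
    assert not up & down
    assert set(sig.index) == up | down
    assigned = sig[sig["signature"] != "unassigned"]
    assert set(assigned.index) <= up | down
    assert (assigned.groupby(level=0).size() == 1).all()
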