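import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribodense as rd
from ribodense.errors import ConfigurationError, SchemaError

from conftest import make_fpkm


class TestTranslationEfficiency:
    def test_arithmetic(self, tiny_scheme):
        t = make_fpkm([("g", "s", "a", 2.0), ("g", "s", "b", 3.0),
                       ("g", "s", "c", 10.0)])
        rec = rd.translation_efficiency(t, tiny_scheme)
        assert rec.iloc[0]["te"] == pytest.approx(2.0)
        assert rec.iloc[0]["steady_state_rna"] == pytest.approx(15.0)

    def test_zero_denominator_undefined(self, tiny_scheme):
        t = make_fpkm([("g", "s", "a", 0.0), ("g", "s", "b", 0.0),
                       ("g", "s", "c", 10.0)])
        rec = rd.translation_efficiency(t, tiny_scheme)
        assert not rec.iloc[0]["te_defined"]
        assert np.isnan(rec.iloc[0]["te"])

    def test_pseudocount_defines_ratio(self, tiny_scheme):
        t = make_fpkm([("g", "s", "a", 0.0), ("g", "s", "b", 0.0),
                       ("g", "s", "c", 10.0)])
        rec = rd.translation_efficiency(t, tiny_scheme, pseudocount=1.0)
        assert rec.iloc[0]["te"] == pytest.approx(11.0)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c, tiny_scheme):
        t = make_fpkm([("g", "s", "a", 2.0), ("g", "s", "b", 3.0),
                       ("g", "s", "c", 10.0)])
        scaled = t.copy()
        scaled["fpkm"] *= c
        r1 = rd.translation_efficiency(t, tiny_scheme).iloc[0]["te"]
        r2 = rd.translation_efficiency(scaled, tiny_scheme).iloc[0]["te"]
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_free_only_denominator(self, tiny_scheme):
        t = make_fpkm([("g", "s", "a", 2.0), ("g", "s", "b", 3.0),
                       ("g", "s", "c", 10.0)])
        rec = rd.translation_efficiency(t, tiny_scheme, denominator="free")
        assert rec.iloc[0]["te"] == pytest.approx(5.0)

    def test_negative_fpkm_rejected(self, tiny_scheme):
        t = make_fpkm([("g", "s", "a", -1.0)])
        with pytest.raises(ConfigurationError):
            rd.translation_efficiency(t, tiny_scheme)

    def test_unknown_fraction_rejected(self, tiny_scheme):
        t = make_fpkm([("g", "s", "zzz", 1.0)])
        with pytest.raises(SchemaError, match="zzz"):
            rd.translation_efficiency(t, tiny_scheme)


class TestSteadyStateRna:
    def test_sum(self):
        assert rd.steady_state_rna([1, 2, 3, 4]) == pytest.approx(10.0)

    def test_all_zero(self):
        assert rd.steady_state_rna([0, 0, 0]) == 0.0

    def test_permutation_invariant(self):
        assert rd.steady_state_rna([4, 1, 3, 2]) == rd.steady_state_rna([1, 2, 3, 4])


class TestDeltaClassification:
    def test_te_only_down(self):
        rec = rd.delta_classification(0.4, 1.0, 0.9, 1.0)
        assert rec["quadrant"] == "te_only" and rec["direction"] == "down"

    def test_inclusive_boundary(self):
        rec = rd.delta_classification(0.5, 1.0, 1.0, 1.0)
        assert rec["quadrant"] == "te_only"
        rec = rd.delta_classification(2.0, 1.0, 1.0, 1.0)
        assert rec["quadrant"] == "te_only" and rec["direction"] == "up"

    def test_both_mixed(self):
        rec = rd.delta_classification(0.45, 1.0, 2.2, 1.0)
        assert rec["quadrant"] == "both" and rec["direction"] == "mixed"

    def test_neither(self):
        rec = rd.delta_classification(1.1, 1.0, 0.9, 1.0)
        assert rec["quadrant"] == "neither" and rec["direction"] == "none"

    def test_rna_only(self):
        rec = rd.delta_classification(1.0, 1.0, 0.3, 1.0)
        assert rec["quadrant"] == "rna_only" and rec["direction"] == "down"

    def test_bad_ns_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.delta_classification(1.0, 0.0, 1.0, 1.0)

    @given(dte=st.floats(0.01, 100), drna=st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_exactly_one_quadrant(self, dte, drna):
        rec = rd.delta_classification(dte, 1.0, drna, 1.0)
        assert rec["quadrant"] in ("te_only", "rna_only", "both", "neither")

    @given(c=st.floats(0.1, 10), dte=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_common_rescale_invariance(self, c, dte):
        a = rd.delta_classification(dte, 1.0, 1.0, 1.0)
        b = rd.delta_classification(dte * c, c, c, c)
        assert a["quadrant"] == b["quadrant"]
        assert a["delta_te"] == pytest.approx(b["delta_te"], rel=1e-9)


class TestQuadrantBookkeeping:
    def test_marginal_identities(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            rows.append({
                "gene_id": f"g{i}",
                **rd.delta_classification(
                    float(rng.lognormal(0, 1)), 1.0,
                    float(rng.lognormal(0, 1)), 1.0)})
        deltas = pd.DataFrame(rows)
        s = rd.quadrant_summary(deltas)
        assert s["te_only"] + s["rna_only"] + s["both"] + s["neither"] == 200
        assert s["te_affected"] == s["te_only"] + s["both"]
        assert s["rna_affected"] == s["rna_only"] + s["both"]


class TestSummarizeMagnitudes:
    def test_uniform_half(self):
        d = pd.DataFrame({"delta_te": [0.5, 0.5], "delta_rna": [1.0, 1.0]})
        out = rd.summarize_magnitudes(d)
        assert out["te_percent_change_geometric"] == pytest.approx(50.0)
        assert out["rna_percent_change_geometric"] == pytest.approx(0.0)

    def test_identity(self):
        d = pd.DataFrame({"delta_te": [1.0], "delta_rna": [1.0]})
        out = rd.summarize_magnitudes(d)
        assert out["te_percent_change_geometric"] == pytest.approx(0.0)

    def test_geometric_mean_closed_form(self):
        d = pd.DataFrame({"delta_te": [0.25, 1.0], "delta_rna": [1.0, 1.0]})
        out = rd.summarize_magnitudes(d)
        assert out["te_percent_change_geometric"] == pytest.approx(50.0)
        assert out["te_percent_change_arithmetic"] == pytest.approx(37.5)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.summarize_magnitudes(pd.DataFrame(columns=["delta_te", "delta_rna"]))


class TestPolysomeAuc:
    def test_uniform_midpoint(self):
        x = np.linspace(0, 1, 11)
        assert rd.polysome_auc(x, np.ones(11), 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_all_before_boundary(self):
        x = [0.0, 0.5, 1.0]
        y = [2.0, 0.0, 0.0]
        assert rd.polysome_auc(x, y, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_triangular_ramp(self):
        # analytic: integral of x on [0.5, 1] over integral on [0, 1] = 0.75
        x = [0.0, 1.0]
        y = [0.0, 1.0]
        assert rd.polysome_auc(x, y, 0.5) == pytest.approx(0.75, abs=1e-9)

    @given(c=st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_scaling_invariance(self, c):
        x = np.linspace(0, 2, 9)
        y = np.array([1, 3, 2, 5, 4, 2, 1, 0.5, 1.5])
        assert rd.polysome_auc(x, c * y, 0.7) == pytest.approx(
            rd.polysome_auc(x, y, 0.7), rel=1e-9)

    def test_rightward_shift_increases_auc(self):
        x = np.linspace(0, 1, 21)
        y1 = np.exp(-((x - 0.3) ** 2) / 0.02)
        y2 = np.exp(-((x - 0.6) ** 2) / 0.02)
        assert rd.polysome_auc(x, y2, 0.5) > rd.polysome_auc(x, y1, 0.5)

    def test_zero_area_undefined(self):
        assert math.isnan(rd.polysome_auc([0, 1], [0, 0], 0.5))

    def test_boundary_outside_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.polysome_auc([0, 1], [1, 1], 2.0)


class TestDdct:
    def test_identity(self):
        assert rd.ddct(20, 10, 20, 10) == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        assert rd.ddct(19, 10, 20, 10) == pytest.approx(2.0)

    def test_log2_ten(self):
        # ddct of log2(10) gives a 10-fold decrease
        dd = math.log2(10)
        assert rd.ddct(20 + dd, 10, 20, 10) == pytest.approx(0.1, rel=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.ddct(float("nan"), 10, 20, 10)


class TestDeltaTable:
    def test_unclassifiable_routing(self, tiny_scheme):
        rows = [("g1", "NS", f, v) for f, v in (("a", 5.0), ("b", 5.0), ("c", 5.0))]
        rows += [("g1", "kd", f, v) for f, v in (("a", 5.0), ("b", 5.0), ("c", 1.0))]
        # g2 has undefined TE in the NS sample (all polysomal)
        rows += [("g2", "NS", f, v) for f, v in (("a", 0.0), ("b", 0.0), ("c", 5.0))]
        rows += [("g2", "kd", f, v) for f, v in (("a", 1.0), ("b", 1.0), ("c", 5.0))]
        recs = rd.translation_efficiency(make_fpkm(rows), tiny_scheme)
        deltas, bad = rd.delta_table(recs, "NS", "kd", return_unclassifiable=True)
        assert bad == ["g2"]
        assert list(deltas["gene_id"]) == ["g1"]
        assert deltas.iloc[0]["delta_te"] == pytest.approx(0.2)

    def test_min_expr_filter(self, tiny_scheme):
        rows = [("g1", "NS", f, 0.1) for f in ("a", "b", "c")]
        rows += [("g1", "kd", f, 0.1) for f in ("a", "b", "c")]
        recs = rd.translation_efficiency(make_fpkm(rows), tiny_scheme)
        deltas, bad = rd.delta_table(recs, "NS", "kd", min_expr=1.0,
                                     return_unclassifiable=True)
        assert bad == ["g1"] and deltas.empty
        deltas2 = rd.delta_table(recs, "NS", "kd", min_expr=0.0)
        assert len(deltas2) == 1
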