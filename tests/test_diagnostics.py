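"""ENC-plot classification, PR2 coordinates, neutrality regression, correlations."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from plastcub import correlation_table, enc_plot, neutrality, pr2_points
from plastcub.diagnostics import CorrelationTable

from oracles import bf_pearson


def _fake_profile(gene="g", enc=50.0, enc_exp=50.0, gc3=0.5, gc12=0.5,
                  a3=1, t3=1, g3=1, c3=1):
    comp = SimpleNamespace(
        gc3=gc3, gc12=gc12,
        counts3={"A": a3, "T": t3, "G": g3, "C": c3})
    ratio = (enc_exp - enc) / enc_exp
    at = a3 + t3
    gcden = g3 + c3
    return SimpleNamespace(
        gene_id=gene, composition=comp, enc_obs=enc, enc_exp=enc_exp,
        enc_ratio=ratio,
        pr2_x=g3 / gcden if gcden else float("nan"),
        pr2_y=a3 / at if at else float("nan"))


class TestEncPlot:
    def test_matching_obs_and_exp_is_inside(self):
        res = enc_plot([_fake_profile(enc=50, enc_exp=50)])
        assert res.n_inside == 1 and res.n_outside == 0
        assert res.table["ENC_ratio"].iloc[0] == 0.0

    def test_toy_classification(self):
        """exp 50/obs 60 -> ratio -0.2 outside; exp 50/obs 49 -> 0.02 inside."""
        res = enc_plot([_fake_profile("a", enc=60, enc_exp=50),
                        _fake_profile("b", enc=49, enc_exp=50)])
        t = res.table.set_index("gene")
        assert t.loc["a", "ENC_ratio"] == pytest.approx(-0.2)
        assert t.loc["a", "class"] == "outside"
        assert t.loc["b", "ENC_ratio"] == pytest.approx(0.02)
        assert t.loc["b", "class"] == "inside"

    def test_undefined_enc_excluded_and_reported(self):
        res = enc_plot([_fake_profile("a"), _fake_profile("b", enc=float("nan"))])
        assert res.excluded == ["b"]
        assert res.n_defined == 1

    def test_census_invariant_to_order(self, mutation_profiles):
        fwd = enc_plot(mutation_profiles)
        rev = enc_plot(list(reversed(mutation_profiles)))
        assert fwd.n_inside == rev.n_inside
        assert fwd.frac_inside + fwd.frac_outside == pytest.approx(1.0)

    def test_high_enc_census(self):
        res = enc_plot([_fake_profile(enc=30), _fake_profile(enc=50)],
                       enc_threshold=45)
        assert res.n_high_enc == 1


class TestPR2:
    def test_balanced_center(self):
        pts = pr2_points([_fake_profile(a3=5, t3=5, g3=7, c3=7)])
        assert pts["x"].iloc[0] == 0.5 and pts["y"].iloc[0] == 0.5

    def test_direct_ratio_lower_right(self):
        """A3=1,T3=3,G3=3,C3=1 -> y=0.25, x=0.75, lower-right quadrant."""
        pts = pr2_points([_fake_profile(a3=1, t3=3, g3=3, c3=1)])
        assert pts["y"].iloc[0] == pytest.approx(0.25)
        assert pts["x"].iloc[0] == pytest.approx(0.75)
        assert pts["quadrant"].iloc[0] == "lower_right"

    def test_zero_denominator_flagged(self):
        pts = pr2_points([_fake_profile(g3=0, c3=0)])
        assert math.isnan(pts["x"].iloc[0])
        assert pts["quadrant"].iloc[0] == "undefined"

    def test_category_labels_attached(self):
        pts = pr2_points([_fake_profile("g1")], categories={"g1": "psa"})
        assert pts["category"].iloc[0] == "psa"


class TestNeutrality:
    def test_identity_line_slope_one(self):
        profs = [_fake_profile(f"g{i}", gc3=x, gc12=x)
                 for i, x in enumerate((0.2, 0.4, 0.6))]
        res = neutrality(profs)
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)

    def test_constant_gc12_slope_zero(self):
        profs = [_fake_profile(f"g{i}", gc3=x, gc12=0.4)
                 for i, x in enumerate((0.2, 0.4, 0.6))]
        assert neutrality(profs).slope == pytest.approx(0.0)

    def test_identical_gc3_flagged(self):
        profs = [_fake_profile(f"g{i}", gc3=0.5, gc12=v)
                 for i, v in enumerate((0.2, 0.4, 0.6))]
        assert math.isnan(neutrality(profs).slope)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            neutrality([_fake_profile()])

    def test_diagonal_ties_count_as_above(self):
        profs = [_fake_profile("a", gc3=0.3, gc12=0.3),
                 _fake_profile("b", gc3=0.4, gc12=0.2),
                 _fake_profile("c", gc3=0.5, gc12=0.6)]
        res = neutrality(profs)
        assert res.n_below_diagonal == 1
        assert res.n_above_diagonal == 2


class TestCorrelationTable:
    def _frame(self):
        return pd.DataFrame({
            "A": [1.0, 2.0, 3.0], "A3": [1.0, 2.0, 4.0],
            "T": [3.0, 1.0, 2.0], "T3": [0.5, 0.5, 0.5]})

    def test_self_correlation_is_one(self):
        res = correlation_table(self._frame(), ["A"], ["A"])
        assert res.r.loc["A", "A"] == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        """x=(1,2,3), y=(1,2,4) -> r ~ 0.9820."""
        res = correlation_table(self._frame(), ["A"], ["A3"])
        assert res.r.loc["A", "A3"] == pytest.approx(0.981981, abs=1e-5)

    def test_transpose_symmetry(self):
        f = self._frame()
        ab = correlation_table(f, ["A"], ["T"])
        ba = correlation_table(f, ["T"], ["A"])
        assert ab.r.loc["A", "T"] == pytest.approx(ba.r.loc["T", "A"])
        assert ab.p.loc["A", "T"] == pytest.approx(ba.p.loc["T", "A"])

    def test_zero_variance_flagged(self):
        res = correlation_table(self._frame(), ["A"], ["T3"])
        assert math.isnan(res.r.loc["A", "T3"])

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            correlation_table(self._frame(), ["A"], ["GC99"])

    def test_stars_thresholds(self):
        ct = CorrelationTable(
            r=pd.DataFrame({"x": [0.9, 0.5, 0.1]}, index=list("abc")),
            p=pd.DataFrame({"x": [0.005, 0.03, 0.5]}, index=list("abc")))
        assert list(ct.stars()["x"]) == ["**", "*", ""]

    def test_pearson_matches_formula_oracle(self, rng):
        """Package r/p equal the explicit t-transform formula to 1e-12."""
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            frame = pd.DataFrame({"A": x, "A3": y})
            res = correlation_table(frame, ["A"], ["A3"])
            r_bf, p_bf = bf_pearson(list(x), list(y))
            assert res.r.loc["A", "A3"] == pytest.approx(r_bf, abs=1e-12)
            assert res.p.loc["A", "A3"] == pytest.approx(p_bf, abs=1e-12)

    def test_profiles_accepted_directly(self, uniform_profiles):
        res = correlation_table(uniform_profiles,
                                ["A", "T", "G", "C", "GC"],
                                ["A3", "T3", "G3", "C3", "GC3"])
        assert res.r.abs().max().max() <= 1.0 + 1e-12
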