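import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from cgimeth.intervals import GenomicInterval
from cgimeth.methylation import (
    benjamini_hochberg,
    call_methylated_by_beta,
    call_methylation_gain,
    cgi_weighted_methylation,
    filter_cpgs,
    mass_spec_5mc_percent,
    samples_in,
    summarise_clones,
)


def make_table(rows, samples=("A", "B")):
    """rows: list of (pos, {sample: (meth, unmeth)})."""
    data = {"chrom": [], "pos": []}
    for s in samples:
        data[f"{s}_meth"], data[f"{s}_unmeth"] = [], []
    for pos, counts in rows:
        data["chrom"].append("chr1")
        data["pos"].append(pos)
        for s in samples:
            m, u = counts[s]
            data[f"{s}_meth"].append(m)
            data[f"{s}_unmeth"].append(u)
    return pd.DataFrame(data)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided exact p by hypergeometric tail enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())


class TestFilterCpgs:
    def test_low_coverage_in_one_sample_removes_cpg(self):
        t = make_table([(10, {"A": (5, 4), "B": (10, 5)}),  # A cov 9 -> drop
                        (20, {"A": (5, 5), "B": (9, 1)})])
        out = filter_cpgs(t, min_coverage=10)
        assert out["pos"].tolist() == [20]

    def test_boundary_coverage_retained(self):
        t = make_table([(10, {"A": (5, 5), "B": (0, 10)})])
        assert len(filter_cpgs(t, min_coverage=10)) == 1

    def test_min_one_is_identity_when_all_covered(self):
        t = make_table([(10, {"A": (1, 0), "B": (0, 1)}),
                        (20, {"A": (3, 3), "B": (2, 2)})])
        pd.testing.assert_frame_equal(filter_cpgs(t, min_coverage=1), t)

    def test_unknown_sample_rejected(self):
        t = make_table([(10, {"A": (5, 5), "B": (5, 5)})])
        with pytest.raises(KeyError, match="unknown sample"):
            filter_cpgs(t, min_coverage=1, samples=["C"])


class TestCgiWeightedMethylation:
    def cgi(self, start, end):
        return GenomicInterval("chr1", start, end, name="cgi1")

    def test_weighted_mean_is_pooled_ratio(self):
        t = make_table([(5, {"A": (5, 5), "B": (0, 1)}),
                        (7, {"A": (10, 0), "B": (0, 1)})])
        out = cgi_weighted_methylation(t, [self.cgi(0, 10)])
        row = out[(out["sample"] == "A")].iloc[0]
        assert row["beta"] == pytest.approx(15 / 20)
        assert row["pooled_meth"] == 15 and row["pooled_unmeth"] == 5

    def test_fully_methylated_is_one(self):
        t = make_table([(5, {"A": (7, 0), "B": (1, 0)})])
        out = cgi_weighted_methylation(t, [self.cgi(0, 10)])
        assert (out["beta"] == 1.0).all()

    def test_empty_cgi_is_missing_not_zero(self):
        t = make_table([(500, {"A": (5, 5), "B": (5, 5)})])
        out = cgi_weighted_methylation(t, [self.cgi(0, 10)])
        assert out["beta"].isna().all()
        assert (out["n_cpgs"] == 0).all()

    def test_invariant_to_cpg_order(self, rng):
        rows = [(int(p), {"A": (int(rng.integers(0, 9)), int(rng.integers(1, 9))),
                          "B": (1, 1)})
                for p in rng.choice(np.arange(1, 100), 20, replace=False)]
        t = make_table(rows)
        shuffled = t.sample(frac=1, random_state=1).reset_index(drop=True)
        a = cgi_weighted_methylation(t, [self.cgi(0, 100)])
        b = cgi_weighted_methylation(shuffled, [self.cgi(0, 100)])
        pd.testing.assert_frame_equal(a, b)


def make_meth(records):
    """records: {cgi: (meth, unmeth)} -> single-sample CgiMethylation frame."""
    rows = [
        (cgi, m / (m + u) if m + u else np.nan, 1, m, u)
        for cgi, (m, u) in records.items()
    ]
    return pd.DataFrame(
        rows, columns=["cgi", "beta", "n_cpgs", "pooled_meth", "pooled_unmeth"]
    )


class TestCallMethylationGain:
    def test_identical_counts_not_gainer(self):
        a = make_meth({"c1": (10, 90)})
        b = make_meth({"c1": (10, 90)})
        out = call_methylation_gain(a, b)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "delta_beta"] == 0.0
        assert not out.loc[0, "is_gainer"]

    def test_strong_gain_matches_enumeration_oracle(self):
        a = make_meth({"c1": (10, 90)})
        b = make_meth({"c1": (60, 40)})
        out = call_methylation_gain(a, b)
        assert out.loc[0, "delta_beta"] == pytest.approx(0.50)
        assert out.loc[0, "p_value"] == pytest.approx(
            fisher_two_sided_oracle(60, 40, 10, 90), rel=1e-9
        )
        assert out.loc[0, "is_gainer"]

    def test_gain_below_threshold_never_gainer(self):
        # huge counts: p tiny but delta 0.19 < 0.20
        a = make_meth({"c1": (1000, 9000)})
        b = make_meth({"c1": (2900, 7100)})
        out = call_methylation_gain(a, b)
        assert out.loc[0, "q_value"] < 1e-10
        assert out.loc[0, "delta_beta"] == pytest.approx(0.19)
        assert not out.loc[0, "is_gainer"]

    def test_missing_cgi_excluded_but_reported(self):
        a = make_meth({"c1": (5, 5), "c2": (0, 0)})
        b = make_meth({"c1": (5, 5), "c2": (3, 3)})
        out = call_methylation_gain(a, b).set_index("cgi")
        assert not out.loc["c2", "tested"]
        assert not out.loc["c2", "is_gainer"]
        assert out.loc["c1", "tested"]


def bh_oracle(p):
    """Independent BH re-implementation: sort + cumulative minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_independent_reimplementation(self, p):
        assert benjamini_hochberg(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_matches_oracle_on_many_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 30)))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p),
                                       atol=1e-12)


class TestCallMethylatedByBeta:
    def test_threshold_inclusive(self):
        betas = pd.DataFrame({"s1": [0.30, 0.29]}, index=["c1", "c2"])
        flags, freq = call_methylated_by_beta(betas)
        assert flags.loc["c1", "s1"] == True  # noqa: E712 (nullable boolean)
        assert flags.loc["c2", "s1"] == False  # noqa: E712

    def test_frequency_excludes_missing(self):
        betas = pd.DataFrame(
            {"s1": [0.9], "s2": [0.8], "s3": [0.5], "s4": [0.1]}, index=["c"]
        )
        _, freq = call_methylated_by_beta(betas)
        assert freq["c"] == pytest.approx(0.75)
        betas_missing = betas.copy()
        betas_missing["s4"] = np.nan
        _, freq2 = call_methylated_by_beta(betas_missing)
        assert freq2["c"] == pytest.approx(1.0)

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            call_methylated_by_beta(pd.DataFrame({"s": [1.2]}))


class TestSummariseClones:
    def test_quarter_error_clone_excluded(self):
        clones = pd.DataFrame(
            [[1, 1, 0, 0, 1, 0, np.nan, np.nan],  # 2/8 = 25% errors
             [1, 1, 1, 1, 0, 0, 0, 0]],
            index=["bad", "good"],
        )
        per_clone, _, excluded = summarise_clones(clones)
        assert excluded == ["bad"]
        assert per_clone["good"] == pytest.approx(0.5)

    def test_mean_over_read_positions(self):
        clones = pd.DataFrame([[1, 1, 1, 1, 0, 0, 0, np.nan]], index=["c"])
        per_clone, per_pos, excluded = summarise_clones(clones)
        assert excluded == []
        assert per_clone["c"] == pytest.approx(4 / 7)

    def test_all_unmethylated_zero(self):
        clones = pd.DataFrame([[0, 0, 0, 0]], index=["c"])
        per_clone, _, _ = summarise_clones(clones)
        assert per_clone["c"] == 0.0


class TestMassSpec5mcPercent:
    @pytest.mark.parametrize(
        "a5, ag, expected",
        [(0, 100, 0.0), (4, 100, 4.0), (5, 95, 100 * 5 / 95)],
    )
    def test_hand_values(self, a5, ag, expected):
        assert mass_spec_5mc_percent(a5, ag) == pytest.approx(expected)

    def test_zero_guanine_rejected(self):
        with pytest.raises(ValueError):
            mass_spec_5mc_percent(1.0, 0.0)
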