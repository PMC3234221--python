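"""Cross-sample variability statistics."""

import numpy as np
import pytest

import noncpg as n
from noncpg.synthetic import SyntheticGenome


def _level_tables(table_factory, levels, coverages=None, context="CpA"):
    """One single-site table per sample with exact levels via large counts."""
    tables = []
    for i, l in enumerate(levels):
        cov = coverages[i] if coverages else 1000
        tables.append(table_factory(
            f"s{i}", [("c", 0, "+", context, int(round(l * cov)), cov)]))
    return tables


class TestCoefficientOfVariation:
    def test_hand_computed_values(self, table_factory):
        t = _level_tables(table_factory, [0.1, 0.2, 0.3])
        cv = n.coefficient_of_variation(t, [("c", 0, "+")], "CpA")
        assert cv.iloc[0] == pytest.approx(0.5)

    def test_zero_heavy_levels(self, table_factory):
        t = _level_tables(table_factory, [0, 0, 0.3])
        cv = n.coefficient_of_variation(t, [("c", 0, "+")], "CpA")
        assert cv.iloc[0] == pytest.approx(np.sqrt(0.03) / 0.1, rel=1e-6)  # ~1.732

    def test_constant_levels_zero_cv(self, table_factory):
        t = _level_tables(table_factory, [0.2, 0.2, 0.2])
        cv = n.coefficient_of_variation(t, [("c", 0, "+")], "CpA")
        assert cv.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_flagged_nan(self, table_factory):
        t = _level_tables(table_factory, [0.0, 0.0, 0.0])
        cv = n.coefficient_of_variation(t, [("c", 0, "+")], "CpA")
        assert np.isnan(cv.iloc[0])


class TestConservationScore:
    def test_hand_computed_capped_example(self):
        cs = n.conservation_score([0.1, 0.2, 0.3], [10, 30, 50], cap=25)
        assert list(cs.weights) == [10, 25, 25]
        assert cs.weighted_mean == pytest.approx(0.225)
        assert cs.score == pytest.approx(0.3208, abs=1e-4)

    def test_equal_coverage_reduces_to_population_cv(self):
        rng = np.random.default_rng(0)
        x = rng.random(8)
        cs = n.conservation_score(x, [20] * 8, cap=25)
        pop_cv = x.std(ddof=0) / x.mean()
        assert cs.score == pytest.approx(pop_cv, rel=1e-12)

    def test_identical_levels_score_zero(self):
        assert n.conservation_score([0.4] * 5, [10] * 5).score == 0.0

    def test_vectorised_matches_scalar(self, table_factory):
        rng = np.random.default_rng(3)
        n_sites, n_samp = 50, 4
        levels = rng.random((n_samp, n_sites))
        covs = rng.integers(5, 60, size=(n_samp, n_sites))
        tables = [
            table_factory(f"s{i}", [
                ("c", p, "+", "CpA", int(round(levels[i, p] * covs[i, p])),
                 int(covs[i, p]))
                for p in range(n_sites)
            ])
            for i in range(n_samp)
        ]
        sites = [("c", p, "+") for p in range(n_sites)]
        vec = n.conservation_scores(tables, sites, "CpA", min_cov=5)
        for p in range(n_sites):
            lv = [t.df.loc[t.df["pos0"] == p, "level"].iloc[0] for t in tables]
            cv = [t.df.loc[t.df["pos0"] == p, "total_count"].iloc[0] for t in tables]
            expect = n.conservation_score(lv, cv)
            got = vec.loc[("c", p, "+")]
            assert got["weighted_mean"] == pytest.approx(expect.weighted_mean)
            if np.isfinite(expect.score):
                assert got["score"] == pytest.approx(expect.score)


class TestPairwisePcc:
    def test_self_correlation_and_anticorrelation(self, table_factory):
        rng = np.random.default_rng(1)
        x = rng.random(40)
        rows_x = [("c", p, "+", "CpA", int(round(v * 1000)), 1000)
                  for p, v in enumerate(x)]
        rows_y = [("c", p, "+", "CpA", int(round((1 - v) * 1000)), 1000)
                  for p, v in enumerate(x)]
        a = table_factory("a", rows_x)
        a2 = table_factory("a2", rows_x)
        b = table_factory("b", rows_y)
        sites = [("c", p, "+") for p in range(40)]
        r = n.pairwise_pcc([a, a2, b], sites)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "a2"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        assert (np.abs(r.fillna(0).values) <= 1 + 1e-12).all()

    def test_cpa_less_conserved_than_cpg(self, cohort):
        samples = cohort["samples"]
        out = {}
        for ctx in ("CpA", "CpG"):
            cons = n.build_consensus(samples, ctx, min_cov=5, min_sample_frac=0.8)
            r = n.pairwise_pcc(samples, cons, min_cov=5)
            iu = np.triu_indices(len(samples), 1)
            out[ctx] = np.nanmean(r.values[iu])
        assert out["CpA"] < out["CpG"]
        assert out["CpG"] > 0.8


class TestExponentialFit:
    def test_recovers_planted_rate(self):
        rng = np.random.default_rng(2)
        fit = n.fit_exponential(rng.exponential(0.02, size=10000))
        assert 0.019 < fit.mean < 0.021
        assert fit.rate == pytest.approx(1 / fit.mean)
        assert fit.ks_p > 0.01

    def test_constant_values_rejected(self):
        fit = n.fit_exponential(np.full(500, 0.05))
        assert fit.ks_stat > 0.3
        assert fit.ks_p < 1e-6

    def test_bimodal_cpg_rejected_exponential_cpa_accepted(self, table_factory):
        rng = np.random.default_rng(4)
        n_sites = 2000
        cpa_lv = rng.exponential(0.03, n_sites).clip(0, 1)
        low = rng.random(n_sites) < 0.3
        cpg_lv = np.where(low, 0.1 * rng.beta(3, 7, n_sites),
                          rng.beta(46, 4, n_sites))

        def tables(levels, ctx):
            return [
                table_factory(f"s{i}", [
                    ("c", p, "+", ctx, int(round(l * 10**5)), 10**5)
                    for p, l in enumerate(levels)
                ])
                for i in range(3)
            ]

        cpa = n.fit_exponential_medians(tables(cpa_lv, "CpA"), "CpA",
                                        median_threshold=0.0)
        cpg = n.fit_exponential_medians(tables(cpg_lv, "CpG"), "CpG",
                                        median_threshold=0.0)
        assert cpa.ks_stat < 0.05
        assert cpg.ks_stat > 5 * cpa.ks_stat

    def test_called_cohort_cpg_medians_worse_fit_than_cpa(self, cohort):
        samples = cohort["samples"]
        cpa = n.fit_exponential_medians(samples, "CpA")
        cpg = n.fit_exponential_medians(samples, "CpG")
        assert cpg.ks_stat > cpa.ks_stat


class TestReduction:
    def test_identity_and_total_loss(self, table_factory):
        ref = [table_factory("r", [("c", 0, "+", "CpA", 500, 1000),
                                   ("c", 1, "+", "CpA", 300, 1000)])]
        assert n.reduction_stats(ref, ref, "CpA") == pytest.approx(0.0)
        none = [table_factory("o", [("c", 0, "+", "CpA", 0, 1000)])]
        assert n.reduction_stats(ref, none, "CpA") == pytest.approx(100.0)
        with pytest.raises(ValueError):
            n.reduction_stats(none, ref, "CpA")

    def test_somatic_reduction_near_truth_implied(self, cohort):
        g, frags = cohort["genome"], cohort["fragments"]
        somatic_truth = n.assign_methylation(g, cpa_rate=0.002, noise_level=0.0,
                                             seed=77)
        somatic = [n.call(n.simulate_reads(g, somatic_truth, frags,
                                           mean_coverage=25, seed=80 + i),
                          g, f"som{i}") for i in range(2)]
        red = n.reduction_stats(cohort["samples"], somatic, "CpA")
        assert red > 60  # near-complete loss of methylated CpAs


class TestMotifMatrix:
    def test_anchor_columns_fixed(self, cohort):
        pfm = n.motif_matrix(cohort["samples"], cohort["genome"], min_cov=8,
                             min_mean_level=0.10, flank=3)
        assert pfm.n_sites > 0
        assert pfm.matrix.loc[0, "C"] == 1.0
        assert pfm.matrix.loc[1, "A"] == 1.0
        assert np.allclose(pfm.matrix.sum(axis=1), 1.0)

    def test_planted_flank_recovered(self, table_factory):
        # every CpA preceded by T and followed (at +2) by G: "...TCAG..."
        seq = ("TCAGG" + "ATTAT") * 120
        g = SyntheticGenome(name="c", sequence=seq)
        cpa_pos = [i + 1 for i in range(0, len(seq) - 5, 10)][1:-1]
        tables = [
            table_factory(f"s{i}", [("c", p, "+", "CpA", 12, 24) for p in cpa_pos])
            for i in range(3)
        ]
        pfm = n.motif_matrix(tables, g, min_cov=10, min_mean_level=0.15, flank=2)
        assert pfm.n_sites == len(cpa_pos)
        assert pfm.matrix.loc[-1, "T"] == 1.0
        assert pfm.matrix.loc[2, "G"] == 1.0

    def test_meme_block_wellformed(self, cohort):
        pfm = n.motif_matrix(cohort["samples"], cohort["genome"], min_cov=8,
                             min_mean_level=0.10, flank=2)
        text = pfm.to_meme()
        assert "MEME version 4" in text and f"nsites= {pfm.n_sites}" in text
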