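"""Normalization, moderated t, BH-FDR and gene-level calling."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from netpharm.config import ComparisonSpec, ConfigError
from netpharm.expression import (
    GeneCallSet,
    adjust_bh,
    call_overexpressed,
    fit_variance_prior,
    intersect_common,
    moderated_ttest,
    normalize,
)
from netpharm.synthetic import GeneratorConfig, simulate

import oracles


def make_matrix(values, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"pr{i}" for i in range(values.shape[0])],
                        columns=samples)


def two_group_annot(n1, n2, case="Gp3", ref="normal_fetal"):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n1 + n2)],
        "group": [case] * n1 + [ref] * n2,
    })


SPEC = ComparisonSpec("Gp3", ("Gp3",), ("normal_fetal",))


class TestNormalize:
    def test_row_zscore_example(self):
        out = normalize(make_matrix([[1.0, 2.0, 3.0]]), "zscore_rows")
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_zero_variance_row_dropped_with_warning(self, caplog):
        matrix = make_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with caplog.at_level(logging.WARNING, logger="netpharm.expression"):
            out = normalize(matrix, "zscore_rows")
        assert list(out.index) == ["pr1"]
        assert "zero-variance" in caplog.text

    def test_center_scale_standardizes_columns(self):
        rng = np.random.default_rng(0)
        out = normalize(make_matrix(rng.normal(5, 2, size=(40, 6))), "center_scale")
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 8))
    def test_row_zscore_invariant(self, seed, n_rows, n_cols):
        rng = np.random.default_rng(seed)
        out = normalize(make_matrix(rng.normal(size=(n_rows, n_cols))), "zscore_rows")
        assert np.abs(out.mean(axis=1)).max() < 1e-12
        assert np.abs(out.std(axis=1, ddof=1) - 1.0).max() < 1e-12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_matrix([[1.0, 2.0]]), "quantile")


class TestModeratedT:
    def test_pooled_t_hand_example(self):
        # case (4,5,6) vs ref (1,2,3): diff 3, pooled s2 = 1, t = 3/sqrt(2/3)
        matrix = make_matrix([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]])
        de = moderated_ttest(matrix, two_group_annot(3, 3), SPEC, d0=0)
        assert de.loc["pr0", "lfc"] == pytest.approx(3.0)
        assert de.loc["pr0", "s2"] == pytest.approx(1.0)
        assert de.loc["pr0", "t"] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert de.loc["pr0", "df"] == 4
        assert de.loc["pr0", "p"] == pytest.approx(
            2 * stats.t.sf(3.0 / np.sqrt(2.0 / 3.0), 4))

    def test_identical_groups_give_null_statistic(self):
        matrix = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        de = moderated_ttest(matrix, two_group_annot(3, 3), SPEC, d0=0)
        assert de.loc["pr0", "lfc"] == 0.0
        assert de.loc["pr0", "t"] == 0.0
        assert de.loc["pr0", "p"] == 1.0

    def test_d0_zero_matches_classic_pooled_t(self):
        rng = np.random.default_rng(11)
        matrix = make_matrix(rng.normal(size=(200, 13)))
        annot = two_group_annot(6, 7)
        de = moderated_ttest(matrix, annot, SPEC, d0=0)
        ref_t, ref_p = stats.ttest_ind(matrix.iloc[:, :6], matrix.iloc[:, 6:],
                                       axis=1, equal_var=True)
        assert np.abs(de["t"].to_numpy() - ref_t).max() < 1e-10
        assert np.abs(de["p"].to_numpy() - ref_p).max() < 1e-10

    def test_infinite_prior_df_pins_variance_to_prior(self):
        rng = np.random.default_rng(5)
        matrix = make_matrix(rng.normal(size=(50, 10)))
        annot = two_group_annot(5, 5)
        s0_2 = 2.5
        de = moderated_ttest(matrix, annot, SPEC, d0=np.inf, s0_2=s0_2)
        expected_t = de["lfc"] / np.sqrt(s0_2 * (1 / 5 + 1 / 5))
        assert np.allclose(de["t"], expected_t, atol=1e-12)

    def test_shrinkage_interpolates_between_limits(self):
        rng = np.random.default_rng(6)
        matrix = make_matrix(rng.normal(size=(100, 12)))
        annot = two_group_annot(6, 6)
        plain = moderated_ttest(matrix, annot, SPEC, d0=0)
        fitted = moderated_ttest(matrix, annot, SPEC)
        d0, s0_2 = fitted.attrs["d0"], fitted.attrs["s0_2"]
        dg = 10
        expected = (d0 * s0_2 + dg * plain["s2"]) / (d0 + dg)
        expected_t = plain["lfc"] / np.sqrt(expected * (1 / 6 + 1 / 6))
        assert np.allclose(fitted["t"], expected_t, atol=1e-10)

    def test_zero_variance_probe_flagged(self, caplog):
        matrix = make_matrix([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]])
        with caplog.at_level(logging.WARNING, logger="netpharm.expression"):
            de = moderated_ttest(matrix, two_group_annot(3, 3), SPEC, d0=0)
        assert np.isinf(de.loc["pr0", "t"])
        assert 0 < de.loc["pr0", "p"] <= np.finfo(float).tiny
        assert "zero moderated variance" in caplog.text

    def test_too_few_samples_rejected(self):
        matrix = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ConfigError):
            moderated_ttest(matrix, two_group_annot(1, 2), SPEC)


class TestVariancePrior:
    def test_moment_fit_recovers_simulated_prior(self):
        # draw gene variances from the hierarchical model and refit
        rng = np.random.default_rng(3)
        d0_true, s0_true, dg, m = 8.0, 1.5, 10, 20000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=m)
        s2 = sigma2 * rng.chisquare(dg, size=m) / dg
        d0, s0_2 = fit_variance_prior(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0_2 == pytest.approx(s0_true, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior_df(self):
        # all genes share sigma2 = 2: log-variance spread is sampling noise only
        rng = np.random.default_rng(4)
        dg = 10
        s2 = 2.0 * rng.chisquare(dg, size=5000) / dg
        d0, s0_2 = fit_variance_prior(s2, dg)
        assert np.isinf(d0)
        assert s0_2 == pytest.approx(2.0, rel=0.05)


class TestBH:
    def test_stepup_hand_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert adjust_bh([0.5]) == pytest.approx([0.5])

    def test_empty_input(self):
        assert adjust_bh([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 50))
    def test_matches_bruteforce_oracle(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        assert np.allclose(adjust_bh(p), oracles.bh_stepup(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(8).uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_bh(p), ref, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_p(self, seed):
        p = np.random.default_rng(seed).uniform(size=30)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestGeneCalls:
    def make_de(self, rows):
        de = pd.DataFrame(rows, columns=["lfc", "t", "p", "q"],
                          index=[f"pr{i}" for i in range(len(rows))])
        de.attrs["comparison"] = "Gp3"
        return de

    def test_any_probe_rule(self):
        de = self.make_de([[1.0, 5.0, 1e-4, 0.01], [-1.0, -1.0, 0.1, 0.2]])
        pm = pd.DataFrame({"probe_id": ["pr0", "pr1"], "gene_symbol": ["G1", "G1"]})
        calls = call_overexpressed(de, pm, alpha=0.05)
        assert calls.called == {"G1"}
        assert calls.best.loc["G1", "probe_id"] == "pr0"

    def test_threshold_and_direction(self):
        de = self.make_de([[1.0, 2.0, 0.03, 0.06], [-2.0, -6.0, 1e-4, 0.01]])
        pm = pd.DataFrame({"probe_id": ["pr0", "pr1"], "gene_symbol": ["G1", "G2"]})
        calls = call_overexpressed(de, pm, alpha=0.05)
        assert calls.called == set()  # G1 above alpha, G2 down-regulated
        assert not calls.best.loc["G2", "called"]

    def test_best_probe_tiebreaks(self):
        # equal q: larger |lfc| wins; equal again: lexicographic probe id
        de = self.make_de([[1.0, 3.0, 0.01, 0.02], [2.0, 4.0, 0.01, 0.02],
                           [-2.0, -4.0, 0.01, 0.02]])
        pm = pd.DataFrame({"probe_id": ["pr0", "pr1", "pr2"],
                           "gene_symbol": ["G1", "G1", "G1"]})
        calls = call_overexpressed(de, pm, alpha=0.05)
        assert calls.best.loc["G1", "probe_id"] == "pr1"

    def test_unmapped_probes_dropped_with_warning(self, caplog):
        de = self.make_de([[1.0, 5.0, 1e-4, 0.01]])
        pm = pd.DataFrame({"probe_id": ["other"], "gene_symbol": ["G9"]})
        with caplog.at_level(logging.WARNING, logger="netpharm.expression"):
            calls = call_overexpressed(de, pm)
        assert calls.called == set()
        assert "probe map" in caplog.text

    def test_alpha_validated(self):
        de = self.make_de([[1.0, 5.0, 1e-4, 0.01]])
        pm = pd.DataFrame({"probe_id": ["pr0"], "gene_symbol": ["G1"]})
        with pytest.raises(ValueError):
            call_overexpressed(de, pm, alpha=1.5)


class TestIntersect:
    def cs(self, genes):
        return GeneCallSet(comparison="x", called=set(genes))

    def test_three_way_intersection(self):
        sets = [self.cs("abc"), self.cs("bcd"), self.cs("bc")]
        assert intersect_common(sets) == {"b", "c"}

    def test_empty_member_empties_result(self):
        assert intersect_common([self.cs("ab"), self.cs("")]) == set()

    def test_bounded_by_smallest_input(self):
        sets = [self.cs("abcdef"), self.cs("ab"), self.cs("abc")]
        assert len(intersect_common(sets)) <= 2

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            intersect_common([self.cs("ab")])


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self):
        """With no planted effect, P(p < alpha) stays within 3 SE of alpha."""
        config = GeneratorConfig(rng_seed=77, effect_lfc=0.0, n_genes=2200,
                                 probes_per_gene_max=1, mean_degree=1.0,
                                 n_planted_common=5, n_planted_specific=0,
                                 n_planted_bridging=0)
        data = simulate(config)
        matrix = normalize(normalize(data.expression, "zscore_rows"), "center_scale")
        spec = ComparisonSpec("Gp3", ("Gp3",), ("normal_fetal", "normal_adult"))
        de = moderated_ttest(matrix, data.annotation, spec)
        m = len(de)
        assert m >= 2000
        for alpha in (0.01, 0.05, 0.1):
            frac = float((de["p"] < alpha).mean())
            band = 3 * np.sqrt(alpha * (1 - alpha) / m)
            assert abs(frac - alpha) <= band
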