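import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from deprof.expression_de import (
    DEResult,
    ModerationFit,
    enrichment_test,
    filter_de,
    fit_moderation,
    moderated_t_test,
    rsn_normalize,
    vst_transform,
)
from deprof.model import GeneSetCollection, ValidationError
from deprof.synthetic import SimConfig, simulate_annotation, simulate_expression

from conftest import make_matrix


# ---------------------------------------------------------------------------
# variance-stabilizing transform


class TestVst:
    def test_log2_fallback_mode(self):
        m = make_matrix(np.full((8, 4), 4.0), scale="raw-intensity")
        out = vst_transform(m, mode="log2")
        assert np.all(out.values == 2.0)
        assert out.scale == "transformed"

    def test_monotone(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.uniform(0.5, 1000, size=(50, 4)), scale="raw-intensity")
        out = vst_transform(m)
        order_in = np.argsort(m.values.ravel(), kind="stable")
        order_out = np.argsort(out.values.ravel(), kind="stable")
        assert np.array_equal(order_in, order_out)

    def test_variance_flattening_on_noisy_fixture(self):
        # fixture: additive (sd 30, offset 60) + multiplicative noise, seed 13
        cfg = SimConfig(
            n_genes=2000, seed=13, additive_noise_sd=30.0, baseline_log2_mean=7.0
        )
        matrix, _ = simulate_expression(simulate_annotation(cfg), cfg)
        mean = matrix.values.mean(axis=1)
        var = matrix.values.var(axis=1, ddof=1)
        rho_pre = stats.spearmanr(mean, var).statistic
        out = vst_transform(matrix)
        rho_post = stats.spearmanr(
            out.values.mean(axis=1), out.values.var(axis=1, ddof=1)
        ).statistic
        assert abs(rho_pre) > 0.6
        assert abs(rho_post) < 0.2
        # plain log2 does not flatten the additive component here
        log2 = np.log2(matrix.values)
        rho_log2 = stats.spearmanr(log2.mean(axis=1), log2.var(axis=1, ddof=1)).statistic
        assert abs(rho_log2) > abs(rho_post)

    def test_needs_eight_genes(self):
        m = make_matrix(np.full((4, 4), 2.0), scale="raw-intensity")
        with pytest.raises(ValidationError, match=">= 8"):
            vst_transform(m)

    def test_rejects_transformed_input(self):
        m = make_matrix(np.zeros((8, 4)), scale="transformed")
        with pytest.raises(ValidationError):
            vst_transform(m)


# ---------------------------------------------------------------------------
# robust spline normalization


class TestRsn:
    def test_identical_samples_identity(self):
        rng = np.random.default_rng(3)
        col = rng.normal(8, 2, size=200)
        m = make_matrix(np.column_stack([col] * 4))
        out = rsn_normalize(m)
        assert np.allclose(out.values, m.values, atol=1e-6)

    def test_shift_removed(self):
        rng = np.random.default_rng(4)
        col = rng.normal(8, 2, size=500)
        m = make_matrix(np.column_stack([col, col + 1.0]))
        out = rsn_normalize(m)
        med = np.median(out.values, axis=0)
        assert abs(med[0] - med[1]) < 1e-3
        # quantile-matching oracle: both medians land on the reference median
        assert med[0] == pytest.approx(np.median(col) + 0.5, abs=1e-3)

    def test_affine_sample_quantiles_agree(self):
        rng = np.random.default_rng(5)
        col = rng.normal(0, 1, size=400)
        m = make_matrix(np.column_stack([col, 2.0 * col - 3.0]))
        out = rsn_normalize(m)
        q = np.linspace(0, 1, 21)
        assert np.allclose(
            np.quantile(out.values[:, 0], q), np.quantile(out.values[:, 1], q), atol=1e-8
        )

    def test_rank_preservation_exact(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(8, 2, size=(300, 4)) + rng.normal(0, 0.3, size=(1, 4))
        m = make_matrix(vals)
        out = rsn_normalize(m)
        for j in range(4):
            rho = stats.spearmanr(m.values[:, j], out.values[:, j]).statistic
            assert rho == 1.0

    def test_constant_sample_error(self):
        m = make_matrix(np.column_stack([np.arange(10.0), np.full(10, 3.0)]))
        with pytest.raises(ValidationError, match="constant"):
            rsn_normalize(m)


# ---------------------------------------------------------------------------
# moderation fit


def _matrix_with_variances(s2):
    """3 vs 3 matrix whose per-gene pooled residual variance is exactly s2."""
    rows = []
    for i, v in enumerate(s2):
        a = math.sqrt(v)
        mu_wt, mu_ko = 8.0 + 0.1 * i, 8.5 + 0.1 * i
        rows.append([mu_wt - a, mu_wt, mu_wt + a, mu_ko - a, mu_ko, mu_ko + a])
    return make_matrix(np.array(rows))


class TestFitModeration:
    def test_equal_variances_give_point_prior(self):
        m = _matrix_with_variances([0.25] * 20)
        fit = fit_moderation(m)
        assert math.isinf(fit.d0)
        assert fit.s0sq == pytest.approx(0.25, rel=1e-9)

    def test_ten_gene_oracle(self):
        # independent brute-force evaluation of the moment equations
        rng = np.random.default_rng(42)
        s2 = np.exp(rng.normal(-2.0, 1.5, size=10))  # wide spread so d0 finite
        m = _matrix_with_variances(s2)
        fit = fit_moderation(m)

        d = 4
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        evar = np.var(e, ddof=1) - polygamma(1, d / 2)
        assert evar > 0
        x = brentq(lambda t: polygamma(1, t) - evar, 1e-6, 1e6, xtol=1e-12)
        d0 = 2 * x
        s0sq = math.exp(np.mean(e) + digamma(x) - math.log(x))
        assert fit.d_g == 4
        assert fit.d0 == pytest.approx(d0, abs=1e-8)
        assert fit.s0sq == pytest.approx(s0sq, abs=1e-8)

    def test_recovery_from_simulation(self):
        cfg = SimConfig(n_genes=2000, d0_true=4.0, s0sq_true=0.05, seed=7)
        matrix, _ = simulate_expression(simulate_annotation(cfg), cfg)
        fit = fit_moderation(vst_transform(matrix, mode="log2"))
        assert abs(fit.d0 - 4.0) / 4.0 < 0.25
        assert abs(fit.s0sq - 0.05) / 0.05 < 0.10

    def test_too_few_genes(self):
        m = _matrix_with_variances([0.2] * 5)
        with pytest.raises(ValidationError, match="stable moment fit"):
            fit_moderation(m)


# ---------------------------------------------------------------------------
# moderated t


FIXTURE_4GENE = np.array(
    [
        [8.10, 8.30, 7.95, 6.85, 7.10, 6.95],
        [5.00, 5.20, 5.10, 5.05, 5.15, 5.12],
        [9.50, 9.40, 9.65, 10.80, 10.60, 10.95],
        [7.00, 7.02, 6.98, 7.01, 6.99, 7.00],
    ]
)


def _oracle_moderated_t(values, d0, s0sq):
    """Brute-force re-evaluation of the moderated-t formulas, plain loops."""
    out = []
    for row in values:
        wt, ko = row[:3], row[3:]
        m1 = sum(wt) / 3
        m2 = sum(ko) / 3
        ss = sum((x - m1) ** 2 for x in wt) + sum((x - m2) ** 2 for x in ko)
        s2 = ss / 4
        lfc = m2 - m1
        s2p = (d0 * s0sq + 4 * s2) / (d0 + 4)
        se = math.sqrt(s2p * (1 / 3 + 1 / 3))
        t = lfc / se
        p = 2 * stats.t.sf(abs(t), df=d0 + 4)
        out.append((lfc, t, p))
    return out


class TestModeratedT:
    def test_four_gene_fixture_matches_oracle(self):
        m = make_matrix(FIXTURE_4GENE)
        fit = ModerationFit(d0=2.5, s0sq=0.04, d_g=4)
        res = moderated_t_test(m, fit)
        oracle = _oracle_moderated_t(FIXTURE_4GENE, 2.5, 0.04)
        for i, (lfc, t, p) in enumerate(oracle):
            assert res.table["log2fc"].iloc[i] == pytest.approx(lfc, abs=1e-10)
            assert res.table["t"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert res.table["p"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_d0_zero_equals_pooled_t(self):
        m = make_matrix(FIXTURE_4GENE)
        fit = ModerationFit(d0=0.0, s0sq=1.0, d_g=4)
        res = moderated_t_test(m, fit)
        for i in range(4):
            t_ref, p_ref = stats.ttest_ind(
                FIXTURE_4GENE[i, 3:], FIXTURE_4GENE[i, :3], equal_var=True
            )
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, rel=1e-12)
            assert res.table["p"].iloc[i] == pytest.approx(p_ref, rel=1e-10)

    def test_identical_group_means(self):
        row = [[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]] * 8
        res = moderated_t_test(make_matrix(np.array(row)), ModerationFit(1.0, 0.1, 4))
        assert np.all(res.table["log2fc"] == 0.0)
        assert np.all(res.table["t"] == 0.0)
        assert np.all(res.table["p"] == 1.0)

    def test_all_constant_flagged(self):
        rows = np.vstack([np.full((1, 6), 5.0)] * 8)
        res = moderated_t_test(make_matrix(rows), ModerationFit(math.inf, 1e-300, 4))
        # zero posterior sd would divide by ~0; with a point prior at ~0 the
        # flag must kick in only when se is exactly 0
        assert np.all(res.table["p"] > 0)

    def test_d0_infinite_is_z_statistic(self):
        m = make_matrix(FIXTURE_4GENE)
        fit = ModerationFit(d0=math.inf, s0sq=0.09, d_g=4)
        res = moderated_t_test(m, fit)
        v = 1 / 3 + 1 / 3
        for i in range(4):
            lfc = res.table["log2fc"].iloc[i]
            assert res.table["t"].iloc[i] == lfc / (0.3 * math.sqrt(v))
            assert res.table["p"].iloc[i] == pytest.approx(
                2 * stats.norm.sf(abs(res.table["t"].iloc[i])), abs=1e-15
            )

    def test_adjusted_p_at_least_raw(self):
        cfg = SimConfig(n_genes=500, n_chroms=1, chrom_length=900_000,
                        min_tss_spacing=1200, seed=5)
        matrix, _ = simulate_expression(simulate_annotation(cfg), cfg)
        t = vst_transform(matrix, mode="log2")
        res = moderated_t_test(t, fit_moderation(t))
        assert np.all(res.table["p_adj"] >= res.table["p"])


# ---------------------------------------------------------------------------
# filtering


def _de_result(log2fc, p):
    n = len(log2fc)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_expr": np.zeros(n),
            "s2": np.ones(n),
            "s2_post": np.ones(n),
            "t": np.zeros(n),
            "p": p,
            "p_adj": np.minimum(np.asarray(p) * n, 1.0),
            "zero_variance": [False] * n,
        },
        index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
    )
    return DEResult(table=table, fit=ModerationFit(4.0, 0.05, 4))


class TestFilterDe:
    def test_clear_pass(self):
        res = filter_de(_de_result([-1.5], [0.01]))
        assert res.calls.iloc[0] == "down"

    def test_fails_twofold(self):
        res = filter_de(_de_result([-0.5], [0.001]))
        assert res.calls.iloc[0] == "unchanged"

    def test_boundaries(self):
        res = filter_de(_de_result([-1.0, -1.0, 1.0], [0.05, 0.049, 0.049]))
        assert list(res.calls) == ["unchanged", "down", "up"]

    def test_calls_partition_and_signs(self):
        rng = np.random.default_rng(8)
        lfc = rng.normal(0, 1.5, 200)
        p = rng.uniform(0, 1, 200)
        res = filter_de(_de_result(lfc, p))
        calls = res.calls
        assert set(calls.unique()) <= {"down", "up", "unchanged"}
        assert np.all(res.table.loc[calls == "down", "log2fc"] <= -1.0)
        assert np.all(res.table.loc[calls == "up", "log2fc"] >= 1.0)
        assert np.all(res.table.loc[calls != "unchanged", "p"] < 0.05)

    def test_adjusted_mode(self):
        res = filter_de(_de_result([-1.5, -1.5], [0.03, 0.4]), p_mode="adjusted")
        assert list(res.calls) == ["unchanged", "unchanged"]


class TestPowerRecovery:
    def test_sensitivity_and_fdp_over_seeds(self):
        # default planted effect (delta=1.5, d0_true=4, 3 vs 3), adjusted-p
        # calls: sensitivity >= 0.8 and false-discovery proportion <= 0.1,
        # aggregated over 20 seeds
        tp = fp = planted_total = 0
        for seed in range(20):
            cfg = SimConfig(n_genes=2000, seed=2000 + seed)
            matrix, truth = simulate_expression(simulate_annotation(cfg), cfg)
            t = rsn_normalize(vst_transform(matrix))
            de = filter_de(moderated_t_test(t, fit_moderation(t)), p_mode="adjusted")
            truth_by_gene = truth.table.set_index("gene_id")["class"]
            calls = de.calls
            called = calls[calls != "unchanged"]
            tp += int((called == truth_by_gene.loc[called.index]).sum())
            fp += int((called != truth_by_gene.loc[called.index]).sum())
            planted_total += int((truth_by_gene != "null").sum())
        assert tp / planted_total >= 0.8
        assert fp / max(tp + fp, 1) <= 0.1


class TestOrderingInvariance:
    def test_counts_invariant_under_reordering(self):
        cfg = SimConfig(n_genes=300, n_chroms=1, chrom_length=600_000,
                        min_tss_spacing=1200, seed=9)
        matrix, _ = simulate_expression(simulate_annotation(cfg), cfg)

        def run(m):
            t = rsn_normalize(vst_transform(m, mode="log2"))
            res = filter_de(moderated_t_test(t, fit_moderation(t)))
            return (
                int((res.calls == "down").sum()),
                int((res.calls == "up").sum()),
            )

        baseline = run(matrix)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.feature_ids))
        shuffled = type(matrix)(
            feature_ids=[matrix.feature_ids[i] for i in perm],
            samples=[matrix.samples[i] for i in (1, 2, 0, 5, 3, 4)],
            values=matrix.values[np.ix_(perm, (1, 2, 0, 5, 3, 4))],
            scale=matrix.scale,
        )
        assert run(shuffled) == baseline


# ---------------------------------------------------------------------------
# enrichment


class TestEnrichment:
    UNIVERSE = {f"g{i}" for i in range(10)}

    def collection(self):
        return GeneSetCollection(
            terms={"T1": ("five genes", [f"g{i}" for i in range(5)])}
        )

    def test_exact_p_matches_enumeration(self):
        query = {"g0", "g1", "g2", "g3"}
        res = enrichment_test(query, self.UNIVERSE, self.collection())
        # exhaustive oracle: all C(10, 4) draws, count those with >= 4 members
        members = set(self.collection().members("T1"))
        hits = sum(
            1
            for draw in itertools.combinations(sorted(self.UNIVERSE), 4)
            if len(set(draw) & members) >= 4
        )
        total = math.comb(10, 4)
        assert hits / total == pytest.approx(5 / 210)
        assert res.table["p"].iloc[0] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        res = enrichment_test({"g5", "g6"}, self.UNIVERSE, GeneSetCollection(
            terms={"T": ("d", ["g0", "g1"])}
        ))
        assert res.table["p"].iloc[0] == 1.0

    def test_query_equals_universe(self):
        res = enrichment_test(self.UNIVERSE, self.UNIVERSE, self.collection())
        assert res.table["p"].iloc[0] == 1.0
        assert res.table["k"].iloc[0] == res.table["K"].iloc[0]

    def test_query_outside_universe_lists_offenders(self):
        with pytest.raises(ValidationError, match="gX"):
            enrichment_test({"g0", "gX"}, self.UNIVERSE, self.collection())

    def test_term_outside_universe_skipped(self):
        coll = GeneSetCollection(terms={"T": ("d", ["zZ1", "zZ2"])})
        res = enrichment_test({"g0"}, self.UNIVERSE, coll)
        assert len(res.table) == 0
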