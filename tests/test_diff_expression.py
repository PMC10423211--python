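import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import chtii


def _welch_oracle(x, y):
    """Straightforward formula evaluation, independent of the implementation."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def _bh_oracle(p):
    """Brute-force definition: q(i) = min over p(j) >= p(i) of p(j)*m/rank(j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {}
    for r, i in enumerate(order, start=1):
        rank[i] = r
    q = []
    for i in range(m):
        q.append(min(min(p[j] * m / rank[j] for j in range(m) if p[j] >= p[i]), 1.0))
    return q


class TestWelchT:
    def test_identical_samples_give_null_statistic(self):
        t, df, p = chtii.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_equal_n_equal_variance_df_limit(self):
        # with equal group sizes and variances Satterthwaite reduces to 2(n-1)
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]
        _, df, _ = chtii.welch_t(x, y)
        assert df == pytest.approx(2 * (len(x) - 1), abs=1e-9)

    def test_textbook_instance_matches_formula(self):
        x, y = [1, 2, 3, 4], [2, 4, 6, 8]
        t, df, p = chtii.welch_t(x, y)
        ot, odf, op = _welch_oracle(x, y)
        assert t == pytest.approx(ot, abs=1e-10)
        assert df == pytest.approx(odf, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_agrees_with_scipy_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            nx, ny = rng.integers(2, 30, size=2)
            x = rng.normal(0, rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), ny)
            t, df, p = chtii.welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_small_groups_and_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            chtii.welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            chtii.welch_t([1.0, 1.0], [2.0, 2.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert chtii.bh_adjust([0.04]).tolist() == [0.04]

    def test_hand_applied_step_up(self):
        q = chtii.bh_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_brute_force_on_permutations(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0, 1, 6).tolist()
        for perm in itertools.permutations(base):
            q = chtii.bh_adjust(list(perm))
            assert q == pytest.approx(_bh_oracle(list(perm)), abs=1e-12)

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 500)
        _, q_ref, _, _ = sm.multipletests(p, method="fdr_bh")
        assert chtii.bh_adjust(p) == pytest.approx(q_ref, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_ranks(self, p):
        q = chtii.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            chtii.bh_adjust([0.5, 1.2])


class TestRunDe:
    def _null_expr(self, n_genes, n_samples, rng):
        return pd.DataFrame(
            rng.normal(5, 1, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_planted_effect_detected_with_high_power(self):
        # 1-SD shift, 200 carriers vs 200 non-carriers: near-certain detection
        rng = np.random.default_rng(17)
        expr = self._null_expr(100, 400, rng)
        carriers = [f"s{i}" for i in range(200)]
        effect_genes = [f"g{i}" for i in range(50)]
        expr.loc[effect_genes, carriers] += 1.0
        res = chtii.run_de(expr, carriers)
        detected = set(res.loc[res["sde"], "gene"])
        power = len(detected & set(effect_genes)) / len(effect_genes)
        assert power >= 0.8

    def test_null_data_yields_no_discoveries(self):
        rng = np.random.default_rng(23)
        expr = self._null_expr(1000, 100, rng)
        res = chtii.run_de(expr, [f"s{i}" for i in range(50)])
        assert res["sde"].sum() <= 2  # BH controls the FDR under the null

    def test_per_gene_type_one_error_near_alpha(self):
        rng = np.random.default_rng(29)
        expr = self._null_expr(2000, 100, rng)
        res = chtii.run_de(expr, [f"s{i}" for i in range(50)])
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_all_samples_as_carriers_is_a_precondition_error(self):
        rng = np.random.default_rng(31)
        expr = self._null_expr(5, 10, rng)
        with pytest.raises(ValueError):
            chtii.run_de(expr, list(expr.columns))

    def test_zero_variance_genes_skipped_and_counted(self):
        rng = np.random.default_rng(37)
        expr = self._null_expr(5, 10, rng)
        expr.iloc[0] = 3.0  # flat gene: untestable
        res = chtii.run_de(expr, [f"s{i}" for i in range(5)])
        assert res.attrs["n_skipped_zero_variance"] == 1
        assert len(res) == 4
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()


class TestTabulatePathways:
    MAP = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "c"],
            "pathway": ["Immune System", "Immune System", "Immune System", "Metabolism"],
        }
    )

    def test_all_in_one_pathway(self):
        assert chtii.tabulate_pathways(["a", "b", "c"], self.MAP)["Immune System"] == 3

    def test_many_to_many_gene_increments_both(self):
        out = chtii.tabulate_pathways(["c"], self.MAP)
        assert out == {"Immune System": 1, "Metabolism": 1}

    def test_unmapped_bucket(self):
        out = chtii.tabulate_pathways(["zzz", "a"], self.MAP)
        assert out["unmapped"] == 1 and out["Immune System"] == 1

    def test_synthetic_map_exact_counts(self, separated_cohort):
        gt = separated_cohort.ground_truth
        vid = sorted(gt.affected_genes)[0]
        affected = gt.affected_genes[vid]
        out = chtii.tabulate_pathways(affected, separated_cohort.pathway_map)
        assert out["Immune System"] == len(affected)
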