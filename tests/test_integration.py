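import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsrlab.core import gsr_matrix
from gsrlab.integration import (
    cumulative_proportion_transform,
    merge_common_genes,
    moderated_t_test,
    transform_matrix,
)
from gsrlab.io import ExpressionMatrix, PhenotypeTable


class TestCumulativeProportion:
    def test_hand_worked_example(self):
        got = cumulative_proportion_transform([4.0, 3.0, 2.0, 1.0])
        assert got == pytest.approx([0.6, 0.3, 0.1, 0.0])

    def test_constant_vector_all_equal(self):
        got = cumulative_proportion_transform([2.0, 2.0, 2.0])
        assert np.all(got == got[0])

    def test_ties_share_the_block_minimum(self):
        got = cumulative_proportion_transform([2.0, 2.0, 1.0])
        assert got[0] == got[1] == pytest.approx(0.2)
        assert got[2] == 0.0

    def test_output_order_equals_input_order(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(size=50)
        t = cumulative_proportion_transform(v)
        assert np.array_equal(np.argsort(v, kind="stable"), np.argsort(t, kind="stable"))

    def test_negative_inputs_shifted_by_minimum(self):
        got = cumulative_proportion_transform([-1.0, 0.0, 1.0])  # -> (0, 1, 2)
        assert got == pytest.approx([0.0, 0.0, 1 / 3])

    def test_bounds_and_zero_attained(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 5.0, size=100)
        t = cumulative_proportion_transform(v)
        assert t.min() == 0.0
        assert t.max() < 1.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            cumulative_proportion_transform([0.0, 0.0])


class TestMergeCommonGenes:
    def _ds(self, name, genes, n_samples=3, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(len(genes), n_samples)),
                index=genes,
                columns=[f"{name}_s{i}" for i in range(n_samples)],
            ),
            dataset_id=name,
        )

    def test_no_drop_needed(self):
        g = [f"g{i}" for i in range(12)]
        d1 = self._ds("d1", g)
        d2 = self._ds("d2", g[:10] + ["x1", "x2"], seed=1)
        cohort = merge_common_genes([d1, d2], min_common=5)
        assert len(cohort.common_genes) == 10
        assert cohort.dropped == []
        assert cohort.merged.n_samples == 6

    def test_outlier_dataset_dropped(self):
        g = [f"g{i}" for i in range(10)]
        d1, d2 = self._ds("d1", g), self._ds("d2", g, seed=1)
        d3 = self._ds("d3", g[:2] + [f"z{i}" for i in range(8)], seed=2)
        cohort = merge_common_genes([d1, d2, d3], min_common=5)
        assert cohort.included == ["d1", "d2"]
        assert cohort.dropped[0][0] == "d3"
        assert len(cohort.common_genes) == 10

    def test_threshold_unreachable_is_error(self):
        d1 = self._ds("d1", ["g1", "g2"])
        with pytest.raises(ValueError, match="cannot reach"):
            merge_common_genes([d1], min_common=10)

    def test_exhaustive_matches_independent_subset_search(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(30)]
        for trial in range(5):
            datasets = [
                self._ds(
                    f"d{k}",
                    sorted(rng.choice(universe, size=rng.integers(10, 25), replace=False)),
                    seed=trial * 10 + k,
                )
                for k in range(4)
            ]
            min_common = 8
            got = merge_common_genes(datasets, min_common=min_common, method="exhaustive")
            # oracle: enumerate keep-subsets, prefer most datasets, then most genes,
            # then lexicographic dataset ids
            best = None
            for r in range(4, 0, -1):
                for keep in combinations(range(4), r):
                    genes = set(datasets[keep[0]].gene_symbols)
                    for i in keep[1:]:
                        genes &= set(datasets[i].gene_symbols)
                    if len(genes) >= min_common:
                        key = (-len(keep), -len(genes), tuple(f"d{i}" for i in keep))
                        if best is None or key < best[0]:
                            best = (key, keep, genes)
                if best:
                    break
            if best is None:
                continue
            assert got.included == [f"d{i}" for i in best[1]]
            assert set(got.common_genes) == best[2]

    def test_sample_sources_recorded(self):
        g = [f"g{i}" for i in range(6)]
        cohort = merge_common_genes(
            [self._ds("d1", g), self._ds("d2", g, seed=3)], min_common=3
        )
        assert set(cohort.sample_sources.values()) == {"d1", "d2"}


def _two_group(n_genes=100, n1=5, n2=5, shift_first=0, seed=0, scale_spread=True):
    rng = np.random.default_rng(seed)
    scales = rng.uniform(0.5, 2.0, size=(n_genes, 1)) if scale_spread else 1.0
    X = rng.normal(size=(n_genes, n1 + n2)) * scales
    X[:shift_first, :n1] += 2.0
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cols = [f"case{i}" for i in range(n1)] + [f"ctl{i}" for i in range(n2)]
    em = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=cols))
    ph = PhenotypeTable(
        {**{f"case{i}": "case" for i in range(n1)}, **{f"ctl{i}": "control" for i in range(n2)}}
    )
    return em, ph


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self):
        em, ph = _two_group(shift_first=10, seed=1)
        res = moderated_t_test(em, ph, "case", prior_df=0)
        X = em.data.loc[res.table.index, ph.samples("case")].to_numpy()
        Y = em.data.loc[res.table.index, ph.samples("control")].to_numpy()
        ref = stats.ttest_ind(X, Y, axis=1)
        np.testing.assert_allclose(res.table["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.table["p"], ref.pvalue, rtol=1e-10)

    def test_identical_variances_make_shrinkage_a_noop(self):
        rng = np.random.default_rng(2)
        n_genes = 50
        # equal per-gene sample variances: identical residual patterns, shifted means
        base = rng.normal(size=6)
        X = np.vstack([base + rng.normal() for _ in range(n_genes)])
        em = ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"case{i}" for i in range(3)] + [f"ctl{i}" for i in range(3)])
        )
        ph = PhenotypeTable(
            {**{f"case{i}": "case" for i in range(3)}, **{f"ctl{i}": "control" for i in range(3)}}
        )
        res = moderated_t_test(em, ph, "case", prior_df=4.0)
        np.testing.assert_allclose(res.table["s2_post"], res.table["s2"], rtol=1e-8)

    def test_null_type_one_error_calibrated(self):
        em, ph = _two_group(n_genes=2000, n1=6, n2=6, shift_first=0, seed=3)
        res = moderated_t_test(em, ph, "case")
        rate = float((res.table["p"] < 0.05).mean())
        assert 0.035 < rate < 0.065

    def test_matches_limma_oracle(self, tmp_path):
        # independent route: Bioconductor limma's lmFit + eBayes on the same matrix
        em, ph = _two_group(n_genes=80, shift_first=10, seed=42)
        res = moderated_t_test(em, ph, "case")
        fixture = tmp_path / "expr.tsv"
        em.data.to_csv(fixture, sep="\t")
        out = tmp_path / "limma.tsv"
        rscript = (
            "suppressMessages(library(limma));"
            f"x <- as.matrix(read.delim('{fixture}', row.names=1));"
            "design <- cbind(Intercept=1, case=as.integer(startsWith(colnames(x), 'case')));"
            "fit <- eBayes(lmFit(x, design));"
            "out <- data.frame(gene=rownames(x), d0=fit$df.prior, s0=fit$s2.prior,"
            "                  t=fit$t[,'case'], p=fit$p.value[,'case']);"
            f"write.table(out, '{out}', sep='\\t', row.names=FALSE, quote=FALSE)"
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t", index_col=0)
        assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert res.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-4)
        np.testing.assert_allclose(res.table.loc[ref.index, "t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res.table.loc[ref.index, "p"], ref["p"], rtol=1e-6)

    def test_q_at_least_p_and_row_order_stable(self):
        em, ph = _two_group(shift_first=20, seed=5)
        res = moderated_t_test(em, ph, "case")
        assert (res.table["q"] >= res.table["p"]).all()
        shuffled = ExpressionMatrix(em.data.sample(frac=1.0, random_state=1))
        res2 = moderated_t_test(shuffled, ph, "case")
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_small_group_is_error(self):
        em, ph = _two_group(n1=1, n2=5)
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t_test(em, ph, "case")


class TestCrossModule:
    def test_transform_preserves_every_gsr_index(self, tiny_expr, tiny_phenotypes, tiny_collection):
        # the cumulative-proportion transform is strictly order-preserving per sample,
        # so GSR indices from raw and transformed matrices agree exactly
        raw = gsr_matrix(tiny_expr, tiny_phenotypes, tiny_collection)
        transformed = gsr_matrix(
            transform_matrix(tiny_expr), tiny_phenotypes, tiny_collection
        )
        pd.testing.assert_frame_equal(raw.data, transformed.data)

    def test_transform_preserves_gsr_on_synthetic_cohort(self, recovery_cohort):
        expr, phenotypes, collection, _ = recovery_cohort
        sub = ExpressionMatrix(expr.data.iloc[:, :30], expr.dataset_id)
        small = type(collection)(collection.sets[:20], collection.source_label)
        raw = gsr_matrix(sub, phenotypes, small)
        transformed = gsr_matrix(transform_matrix(sub), phenotypes, small)
        pd.testing.assert_frame_equal(raw.data, transformed.data)
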