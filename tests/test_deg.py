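"""Rank-sum marker detection, adjustment, subcluster rule, signature
extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from metasig import (CellAnnotation, DEGConfig, ValidationError,
                     adjust_pvalues, detect_origin_subclusters,
                     extract_signature, wilcoxon_deg)

from conftest import make_normalized

NOFILTER = DEGConfig(min_pct=0.0, logfc_threshold=0.0)


def two_group_matrix(rng, n_genes=40, n_in=12, n_out=14, shift_genes=0,
                     shift=0.0):
    vals = np.log1p(rng.gamma(1.0, 1.0, size=(n_genes, n_in + n_out)))
    if shift_genes:
        vals[:shift_genes, :n_in] += shift
    m = make_normalized(vals)
    labels = pd.Series(["A"] * n_in + ["B"] * n_out, index=m.cells)
    return m, labels


class TestWilcoxon:
    def test_exact_small_sample_p(self):
        """{1,2,3} vs {4,5,6}: most extreme rank-sum, two-sided p = 2/20."""
        m = make_normalized(np.array([[1.0, 2, 3, 4, 5, 6]]))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.cells)
        out = wilcoxon_deg(m, labels, "A", NOFILTER)
        assert out["p_raw"].iloc[0] == pytest.approx(0.1)

    def test_identical_expression_filtered_out(self, rng):
        # gene identical across groups: log_fc 0, dropped by the fold filter
        vals = np.vstack([np.tile([1.0, 2.0, 3.0], 2),
                          np.r_[np.full(3, 2.0), np.full(3, 0.1)]])
        m = make_normalized(vals)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=m.cells)
        out = wilcoxon_deg(m, labels, "A", DEGConfig())
        assert "g0" not in set(out["gene"])
        assert "g1" in set(out["gene"])

    def test_tiny_group_rejected(self):
        m = make_normalized(np.arange(8.0).reshape(2, 4))
        labels = pd.Series(["A", "A", "B", "B"], index=m.cells)
        with pytest.raises(ValidationError, match="at least 3"):
            wilcoxon_deg(m, labels, "A", NOFILTER)

    def test_all_tied_gene_p_one(self):
        vals = np.vstack([np.ones(8), np.r_[np.zeros(4) + 2, np.zeros(4)]])
        m = make_normalized(vals)
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=m.cells)
        out = wilcoxon_deg(m, labels, "A", NOFILTER).set_index("gene")
        assert out.loc["g0", "p_raw"] == 1.0
        assert out.loc["g0", "log_fc"] == pytest.approx(0.0)

    def test_planted_shift_significant_up(self, rng):
        m, labels = two_group_matrix(rng, n_genes=60, n_in=50, n_out=50,
                                     shift_genes=1, shift=2.0)
        out = wilcoxon_deg(m, labels, "A").set_index("gene")
        assert out.loc["g0", "significant"]
        assert out.loc["g0", "direction"] == "up"
        assert out.loc["g0", "p_adj"] < 0.05

    def test_prefilter_on_min_pct_and_logfc(self, rng):
        m, labels = two_group_matrix(rng, n_genes=30)
        strict = wilcoxon_deg(m, labels, "A",
                              DEGConfig(min_pct=0.99, logfc_threshold=0.0))
        assert len(strict) <= len(wilcoxon_deg(m, labels, "A", NOFILTER))

    def test_swap_negates_logfc_preserves_p(self, rng):
        m, labels = two_group_matrix(rng, n_genes=25, shift_genes=5, shift=1.0)
        a = wilcoxon_deg(m, labels, "A", NOFILTER).set_index("gene")
        b = wilcoxon_deg(m, labels, "B", NOFILTER).set_index("gene")
        shared = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[shared, "log_fc"],
                                   -b.loc[shared, "log_fc"], atol=1e-12)
        np.testing.assert_allclose(a.loc[shared, "p_raw"],
                                   b.loc[shared, "p_raw"], atol=1e-12)

    def test_normal_approx_close_to_exact(self):
        """Asymptotic p within 0.02 of exact enumeration at n=8-10."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            n1, n2 = rng.integers(8, 11, size=2)
            x, y = rng.normal(size=int(n1)), rng.normal(size=int(n2))
            pe = mannwhitneyu(x, y, alternative="two-sided",
                              method="exact").pvalue
            pa = mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue
            worst = max(worst, abs(pe - pa))
        assert worst < 0.02

    def test_global_null_bonferroni_rarely_fires(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m, labels = two_group_matrix(r, n_genes=1000, n_in=100, n_out=100)
            out = wilcoxon_deg(m, labels, "A", DEGConfig(min_pct=0.0,
                                                         logfc_threshold=0.0))
            hits += int(out["significant"].sum() > 0)
        assert hits <= 1      # >= 95% of runs clean


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.01], method)[0] == pytest.approx(0.01)

    def test_bonferroni_formula(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.04], "bonferroni"),
                                   [0.02, 0.08])

    def test_bh_matches_stepup_oracle(self, rng):
        def bh_oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(10):
            p = rng.uniform(size=15)
            np.testing.assert_allclose(adjust_pvalues(p, "bh"), bh_oracle(p),
                                       rtol=1e-12)
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.9], "bh"),
            bh_oracle([0.01, 0.02, 0.03, 0.9]), rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw(self, p):
        for method in ("bonferroni", "bh"):
            adj = adjust_pvalues(p, method)
            assert (adj >= np.asarray(p) - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()


def _ann(cluster_sizes_ln):
    """clusters with given (size, n_ln) pairs."""
    rows = []
    i = 0
    for k, (size, n_ln) in enumerate(cluster_sizes_ln):
        for j in range(size):
            rows.append({"cell_id": f"c{i}", "sample": "LN1" if j < n_ln else "PT1",
                         "origin_class": "LN" if j < n_ln else "PT",
                         "cluster": f"k{k}"})
            i += 1
    return CellAnnotation(pd.DataFrame(rows))


class TestOriginSubclusters:
    def test_strict_ninety_percent_rule(self):
        ann = _ann([(100, 91), (100, 90)])
        assert detect_origin_subclusters(ann, "LN") == ["k0"]

    def test_composition_sweep(self):
        ann = _ann([(100, 95), (100, 91), (100, 90), (100, 50), (100, 0)])
        assert detect_origin_subclusters(ann, "LN") == ["k0", "k1"]

    def test_cell_order_invariant_and_unique(self):
        ann = _ann([(50, 49), (50, 48)])
        shuffled = CellAnnotation(
            ann.table.sample(frac=1, random_state=1).reset_index(drop=True))
        assert detect_origin_subclusters(shuffled, "LN") == \
            detect_origin_subclusters(ann, "LN")

    def test_no_clusters_annotated(self):
        ann = _ann([(10, 5)])
        ann.table["cluster"] = None
        with pytest.raises(ValidationError, match="cluster"):
            detect_origin_subclusters(ann, "LN")


class TestExtractSignature:
    def _table(self, n_up, n_down=5):
        rows = []
        for i in range(n_up):
            rows.append({"gene": f"up{i:02d}", "group": "k", "log_fc": 1 + i * 0.01,
                         "pct_in": 0.5, "pct_out": 0.1, "p_raw": 1e-6,
                         "p_adj": 1e-5 * (i + 1), "direction": "up",
                         "significant": True})
        for i in range(n_down):
            rows.append({"gene": f"dn{i:02d}", "group": "k", "log_fc": -1.0,
                         "pct_in": 0.1, "pct_out": 0.5, "p_raw": 1e-6,
                         "p_adj": 1e-6, "direction": "down",
                         "significant": True})
        return pd.DataFrame(rows)

    def test_exactly_top_n_returned_deterministically(self):
        sig1 = extract_signature(self._table(30), top_n=20)
        sig2 = extract_signature(self._table(30).sample(frac=1, random_state=2),
                                 top_n=20)
        assert len(sig1) == 20
        assert sig1.genes == sig2.genes
        assert sig1.genes == [f"up{i:02d}" for i in range(20)]

    def test_fewer_available_warns(self):
        with pytest.warns(UserWarning, match="only 12"):
            sig = extract_signature(self._table(12), top_n=20)
        assert len(sig) == 12

    def test_none_available_errors(self):
        with pytest.raises(ValidationError, match="upregulated"):
            extract_signature(self._table(0), top_n=20)

    def test_planted_largest_shifts_win(self, rng):
        vals = np.log1p(rng.gamma(1.0, 1.0, size=(100, 80)))
        vals[:20, :40] += 2.0          # the 20 planted strongest markers
        vals[20:30, :40] += 0.3        # weaker, sub-threshold shifts
        m = make_normalized(vals)
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=m.cells)
        deg = wilcoxon_deg(m, labels, "A")
        sig = extract_signature(deg, top_n=20)
        assert set(sig.genes) == {f"g{i}" for i in range(20)}
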