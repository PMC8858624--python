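"""Growth-curve split threshold and the iterative malignancy classifier."""

import numpy as np
import pandas as pd
import pytest

from metasig import (DivisionConfig, GeneSet, ModuleScoreConfig,
                     ValidationError, derive_reference_sets,
                     find_split_threshold, iterate_division, lognormalize,
                     score_difference)
from metasig.malignancy import (MALIGNANT, NON_MALIGNANT, DegenerateInputError,
                                SplitCurve, classify_by_threshold)
from metasig.simulate import division_recovery_scenario

from conftest import make_normalized


class TestScoreDifference:
    def test_equal_scores_all_zero(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        curve = score_difference(s, s)
        assert (curve.values == 0).all()

    def test_sorted_arithmetic(self):
        mal = pd.Series([1.0, 3.0], index=["a", "b"])
        non = pd.Series([0.5, 1.0], index=["a", "b"])
        curve = score_difference(mal, non)
        np.testing.assert_allclose(curve.values, [0.5, 2.0])
        assert list(curve.cells) == ["a", "b"]

    def test_matches_independent_sort(self, rng):
        cells = [f"c{i}" for i in range(50)]
        mal = pd.Series(rng.normal(size=50), index=cells)
        non = pd.Series(rng.normal(size=50), index=cells)
        curve = score_difference(mal, non)
        oracle = np.sort((mal - non).to_numpy())
        np.testing.assert_allclose(curve.values, oracle, rtol=0, atol=0)

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ValidationError, match="different cells"):
            score_difference(pd.Series([1.0], index=["a"]),
                             pd.Series([1.0], index=["b"]))


class TestFindSplitThreshold:
    def test_worked_example(self):
        """Largest of the 5 consecutive gaps sits between -0.40 and 0.30."""
        curve = SplitCurve(values=[-0.50, -0.45, -0.40, 0.30, 0.35, 0.40],
                           cells=list("abcdef"))
        assert find_split_threshold(curve) == pytest.approx(-0.05)

    def test_two_component_mixture(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals = np.sort(np.concatenate([r.normal(-1, 0.05, 200),
                                           r.normal(1, 0.05, 200)]))
            thr = find_split_threshold(
                SplitCurve(vals, np.arange(400).astype(object)))
            hits += -0.7 < thr < 0.7
        assert hits >= 99

    def test_constant_curve_degenerate(self):
        curve = SplitCurve(values=[1.0] * 6, cells=list("abcdef"))
        with pytest.raises(DegenerateInputError):
            find_split_threshold(curve)

    def test_too_short_curve(self):
        with pytest.raises(DegenerateInputError):
            find_split_threshold(SplitCurve([0.0, 1.0], ["a", "b"]))

    def test_threshold_strictly_inside_range(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            vals = np.sort(r.normal(size=60))
            thr = find_split_threshold(
                SplitCurve(vals, np.arange(60).astype(object)))
            assert vals.min() < thr < vals.max()

    def test_boundary_cell_is_non_malignant(self):
        curve = SplitCurve(values=[-1.0, 0.0, 1.0], cells=list("abc"))
        labels = classify_by_threshold(curve, 0.0)
        assert labels["b"] == NON_MALIGNANT       # strict '>' for malignant
        assert labels["c"] == MALIGNANT


class TestDeriveReferenceSets:
    def _planted(self, rng, shift=3.0):
        vals = np.log1p(rng.gamma(1.0, 1.0, size=(300, 60)))
        vals[:60, :30] += shift                  # 60 genes up in 'malignant'
        vals[60:120, 30:] += shift               # 60 genes up in 'non-malignant'
        m = make_normalized(vals)
        labels = pd.Series([MALIGNANT] * 30 + [NON_MALIGNANT] * 30,
                           index=m.cells)
        return m, labels

    def test_planted_markers_recovered(self, rng):
        m, labels = self._planted(rng)
        mal, non = derive_reference_sets(m, labels, DivisionConfig())
        assert len(mal) == 50
        assert set(mal.genes) <= {f"g{i}" for i in range(60)}
        assert set(non.genes) <= {f"g{i}" for i in range(60, 120)}

    def test_label_swap_swaps_sets(self, rng):
        m, labels = self._planted(rng)
        mal, non = derive_reference_sets(m, labels, DivisionConfig())
        swapped = labels.map({MALIGNANT: NON_MALIGNANT,
                              NON_MALIGNANT: MALIGNANT})
        mal2, non2 = derive_reference_sets(m, swapped, DivisionConfig())
        assert mal.genes == non2.genes
        assert non.genes == mal2.genes

    def test_no_signal_errors(self, rng):
        vals = np.log1p(rng.gamma(1.0, 1.0, size=(100, 40)))
        m = make_normalized(vals)
        labels = pd.Series([MALIGNANT] * 20 + [NON_MALIGNANT] * 20,
                           index=m.cells)
        with pytest.raises(ValidationError, match="alpha_refresh"):
            derive_reference_sets(m, labels, DivisionConfig())

    def test_tiny_class_rejected(self, rng):
        m, labels = self._planted(rng)
        labels.iloc[2:30] = NON_MALIGNANT
        with pytest.raises(ValidationError, match="at least 3"):
            derive_reference_sets(m, labels, DivisionConfig())


class TestIterateDivision:
    def test_planted_recovery_converges(self):
        m, ann, truth, im, inm = division_recovery_scenario(seed=0)
        norm = lognormalize(m)
        state = iterate_division(norm, list(m.cells), im, inm,
                                 DivisionConfig(), ModuleScoreConfig(seed=0))
        truth_labels = ann.table.set_index("cell_id")["truth_label"]
        acc = (state.labels.reindex(truth_labels.index) == truth_labels).mean()
        assert state.converged
        assert state.iteration <= 10
        assert acc >= 0.95

    def test_convergence_bookkeeping(self):
        m, ann, truth, im, inm = division_recovery_scenario(seed=3)
        norm = lognormalize(m)
        state = iterate_division(norm, list(m.cells), im, inm,
                                 DivisionConfig(), ModuleScoreConfig(seed=3))
        assert state.converged == (state.history[-1] == 0)
        assert len(state.history) == state.iteration

    def test_preset_threshold_used_first_iteration(self):
        m, ann, truth, im, inm = division_recovery_scenario(seed=1)
        norm = lognormalize(m)
        cfg = DivisionConfig(initial_threshold=-0.02, max_iter=1)
        state = iterate_division(norm, list(m.cells), im, inm, cfg,
                                 ModuleScoreConfig(seed=1))
        assert state.threshold == pytest.approx(-0.02)
        # the preset rule: score difference > -0.02 is malignant
        mal_cells = state.labels[state.labels == MALIGNANT].index
        assert len(mal_cells) > 0

    def test_cell_order_invariance(self):
        m, ann, truth, im, inm = division_recovery_scenario(
            seed=2, n_malignant=60, n_non=40, n_genes=400)
        norm = lognormalize(m)
        cfg, scfg = DivisionConfig(), ModuleScoreConfig(seed=2)
        cells = list(m.cells)
        a = iterate_division(norm, cells, im, inm, cfg, scfg)
        b = iterate_division(norm, cells[::-1], im, inm, cfg, scfg)
        pd.testing.assert_series_equal(a.labels.sort_index(),
                                       b.labels.sort_index())

    def test_monotone_in_planted_shift(self):
        mean_acc = []
        for shift in (1.0, 2.0, 3.0):
            accs = []
            for seed in range(3):
                m, ann, truth, im, inm = division_recovery_scenario(
                    seed=seed, shift=shift)
                norm = lognormalize(m)
                state = iterate_division(norm, list(m.cells), im, inm,
                                         DivisionConfig(),
                                         ModuleScoreConfig(seed=seed))
                tl = ann.table.set_index("cell_id")["truth_label"]
                accs.append((state.labels.reindex(tl.index) == tl).mean())
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] <= mean_acc[1] + 1e-9
        assert mean_acc[1] <= mean_acc[2] + 1e-9

    def test_disjoint_reference_sets_rejected(self, rng):
        vals = np.log1p(rng.gamma(1.0, 1.0, size=(20, 10)))
        m = make_normalized(vals)
        with pytest.raises(ValidationError, match="no gene"):
            iterate_division(m, list(m.cells), GeneSet("a", ["zz1"]),
                             GeneSet("b", ["zz2"]))
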