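"""TSS binning geometry and chromatin→expression model fitting."""

import numpy as np
import pandas as pd
import pytest

from xspecies.chromatin import (
    BinScheme,
    CorrelationProfile,
    SignalTensor,
    bin_signals,
    correlation_profile,
    fit_organism_model,
    fit_universal_model,
    predict_expression,
    select_best_bins,
    tf_subset_curve,
    ChromatinExpressionModel,
    UniversalChromatinModel,
)
from xspecies.io_core import (
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    ValidationError,
)
from xspecies.synthetic import simulate_chromatin


def expr_of(values, genes, species="org0"):
    meta = pd.DataFrame(
        {"species": species, "stage_index": [0], "stage_label": ["bulk"],
         "tissue": ""},
        index=pd.Index(["expr"], name="sample"),
    )
    return ExpressionMatrix(
        species, pd.DataFrame({"expr": values}, index=genes), meta
    )


def naive_bin_oracle(arr, tss, strand, scheme):
    """Per-base loop implementation of strand-aware TSS binning."""
    out = np.zeros(scheme.n_bins)
    c, w = scheme.center, scheme.bin_width
    for b in range(scheme.n_bins):
        total = 0.0
        for off in range(w):
            if strand == "-":
                pos = tss - (b - c) * w - (w - w // 2) + 1 + off
            else:
                pos = tss + (b - c) * w - w // 2 + off
            if 0 <= pos < arr.size:
                total += arr[pos]
        out[b] = total / w
    return out


class TestBinScheme:
    def test_requires_odd_bin_count(self):
        with pytest.raises(ValidationError):
            BinScheme(n_bins=10)
        with pytest.raises(ValidationError):
            BinScheme(bin_width=0)

    def test_impulse_near_tss_lands_in_center_bin_on_both_strands(self):
        scheme = BinScheme(n_bins=5, bin_width=100)
        arr = np.zeros(5000)
        tss = 2500
        arr[tss + 10] = 1.0
        track = CoverageTrack("x", {"chr1": arr})
        plus = bin_signals(
            {"m": track}, [GenomicInterval("chr1", tss, tss + 1, "+", "g")],
            scheme,
        )
        assert plus.values[0, 0].argmax() == scheme.center
        arr2 = np.zeros(5000)
        arr2[tss - 10] = 1.0
        minus = bin_signals(
            {"m": CoverageTrack("x", {"chr1": arr2})},
            [GenomicInterval("chr1", tss, tss + 1, "-", "g")],
            scheme,
        )
        assert minus.values[0, 0].argmax() == scheme.center

    def test_matches_naive_per_base_oracle(self, rng):
        scheme = BinScheme(n_bins=7, bin_width=13)
        arr = rng.random(600)
        track = CoverageTrack("x", {"chr1": arr})
        for _ in range(20):
            tss = int(rng.integers(0, 600))
            strand = str(rng.choice(["+", "-"]))
            iv = GenomicInterval("chr1", tss, tss + 1, strand, "g")
            tensor = bin_signals({"m": track}, [iv], scheme)
            want = naive_bin_oracle(arr, tss, strand, scheme)
            np.testing.assert_allclose(tensor.values[0, 0], want)

    def test_genome_reversal_with_strand_flip_is_invariant(self, rng):
        scheme = BinScheme(n_bins=5, bin_width=10)
        length = 400
        arr = rng.random(length)
        genes = []
        for i in range(10):
            s = int(rng.integers(60, length - 60))
            genes.append(GenomicInterval("chr1", s, s + 30,
                                         str(rng.choice(["+", "-"])), f"g{i}"))
        fwd = bin_signals({"m": CoverageTrack("x", {"chr1": arr})}, genes, scheme)
        flipped = {"+": "-", "-": "+"}
        mirrored_genes = [
            GenomicInterval("chr1", length - iv.end, length - iv.start,
                            flipped[iv.strand], iv.name)
            for iv in genes
        ]
        rev = bin_signals(
            {"m": CoverageTrack("x", {"chr1": arr[::-1].copy()})},
            mirrored_genes, scheme,
        )
        np.testing.assert_allclose(rev.values, fwd.values)

    def test_missing_chromosome_is_an_error(self):
        scheme = BinScheme(n_bins=3, bin_width=10)
        track = CoverageTrack("x", {"chr1": np.ones(100)})
        with pytest.raises(ValidationError):
            bin_signals({"m": track},
                        [GenomicInterval("chr2", 50, 51, "+", "g")], scheme)


class TestCorrelationProfile:
    def _tensor(self, values, marks=None):
        n_genes, n_marks, n_bins = values.shape
        return SignalTensor(
            organism="org0",
            genes=[f"g{i}" for i in range(n_genes)],
            marks=marks or [f"m{k}" for k in range(n_marks)],
            scheme=BinScheme(n_bins=n_bins, bin_width=10),
            values=values,
        )

    def test_signal_equal_to_expression_gives_r_one_at_that_bin(self, rng):
        e = rng.random(50) * 10
        values = rng.random((50, 1, 3))
        values[:, 0, 1] = e
        tensor = self._tensor(values)
        prof = correlation_profile(tensor, expr_of(e, tensor.genes))
        assert prof.raw[0, 1] == pytest.approx(1.0)
        assert np.abs(prof.normalized[0]).max() == pytest.approx(1.0)

    def test_generative_sign_flip_flips_the_profile(self):
        tensors, exprs, truth = simulate_chromatin(
            600, ["act", "rep"], 11, np.array([1.0, -1.0]), 0.2, 1, [1.0], 4
        )
        prof = correlation_profile(tensors[0], exprs[0])
        assert prof.raw[0, truth.peak_bins[0]] > 0.5
        assert prof.raw[1, truth.peak_bins[1]] < -0.5

    def test_matches_direct_correlation_oracle(self, rng):
        values = rng.random((30, 2, 5))
        e = rng.random(30) * 5
        tensor = self._tensor(values)
        prof = correlation_profile(tensor, expr_of(e, tensor.genes))
        y = np.log(e + 1)
        for m in range(2):
            for b in range(5):
                want = np.corrcoef(np.log(values[:, m, b] + 1), y)[0, 1]
                assert prof.raw[m, b] == pytest.approx(want)


class TestSelectBestBins:
    def _profile(self, raw):
        raw = np.asarray(raw, float)
        return CorrelationProfile(
            marks=[f"m{k}" for k in range(raw.shape[0])],
            raw=raw, normalized=raw,
            scheme=BinScheme(n_bins=raw.shape[1], bin_width=10),
        )

    def test_single_bin_scheme(self):
        assert select_best_bins(self._profile([[0.4]])) == {"m0": 0}

    def test_symmetric_tie_prefers_upstream_nearest_bin(self):
        prof = self._profile([[0.0, 0.5, 0.0, 0.5, 0.0]])
        # bins 1 and 3 tie; both one step from center bin 2; upstream wins
        assert select_best_bins(prof) == {"m0": 1}

    def test_planted_peak_bin_recovered(self, rng):
        # distinguishable bins: independent noise everywhere, signal at one
        n_genes, n_bins, peak = 400, 9, 6
        e = rng.random(n_genes) * 10
        values = rng.random((n_genes, 1, n_bins))
        values[:, 0, peak] = e + 0.1 * rng.random(n_genes)
        tensor = SignalTensor(
            organism="org0", genes=[f"g{i}" for i in range(n_genes)],
            marks=["m"], scheme=BinScheme(n_bins=n_bins, bin_width=10),
            values=values,
        )
        prof = correlation_profile(tensor, expr_of(e, tensor.genes))
        assert select_best_bins(prof) == {"m": peak}


class TestOrganismModel:
    def test_noiseless_single_mark_recovers_unit_coefficient(self):
        tensors, exprs, truth = simulate_chromatin(
            300, ["m"], 9, np.array([1.0]), 0.0, 1, [1.0], 6
        )
        fit = fit_organism_model(tensors[0], exprs[0], folds=5, seed=0)
        assert fit.coef[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.cv_accuracy == pytest.approx(1.0, abs=1e-9)

    def test_irrelevant_mark_gets_no_weight(self):
        tensors, exprs, truth = simulate_chromatin(
            2000, ["big", "null"], 9, np.array([2.0, 0.0]), 0.1, 1, [1.0], 7
        )
        peak = dict(zip(truth.marks, truth.peak_bins))
        fit = fit_organism_model(tensors[0], exprs[0], folds=5, seed=0,
                                 best_bins=peak)
        assert abs(fit.coef[1]) < 0.05
        assert fit.importance[0] > 0.95
        assert fit.importance[1] < 0.05

    def test_duplicate_feature_raises_collinearity_error(self):
        rng = np.random.default_rng(0)
        values = np.zeros((50, 2, 1))
        values[:, 0, 0] = rng.random(50)
        values[:, 1, 0] = values[:, 0, 0]
        tensor = SignalTensor(
            organism="org0", genes=[f"g{i}" for i in range(50)],
            marks=["a", "b"], scheme=BinScheme(n_bins=1, bin_width=10),
            values=values,
        )
        e = rng.random(50)
        with pytest.raises(ValidationError, match="collinear"):
            fit_organism_model(tensor, expr_of(e, tensor.genes), folds=3, seed=0)

    def test_model_results_wrapper_summary(self):
        tensors, exprs, _ = simulate_chromatin(
            200, ["a", "b"], 9, np.array([0.5, -0.5]), 0.3, 1, [1.0], 8
        )
        res = ChromatinExpressionModel(tensors[0], exprs[0]).fit(folds=4, seed=0)
        assert set(res.params.index) == {"a", "b"}
        assert res.importance.sum() == pytest.approx(1.0)
        text = res.summary()
        assert "cross-validated" in text and "coef" in text


class TestUniversalModel:
    def test_shared_coefficients_with_scale_differences_fit_almost_exactly(self):
        tensors, exprs, _ = simulate_chromatin(
            500, ["a", "b"], 9, np.array([0.8, -0.3]), 0.0, 3,
            [1.0, 4.0, 0.25], 9,
        )
        fit = fit_universal_model(list(zip(tensors, exprs)), folds=4, seed=0)
        for r in fit.cv_per_organism.values():
            assert r > 0.999

    def test_opposite_sign_coefficients_hurt_the_universal_model(self):
        t_a, e_a, _ = simulate_chromatin(
            500, ["m"], 9, np.array([1.0]), 0.1, 1, [1.0], 10
        )
        t_b, e_b, _ = simulate_chromatin(
            500, ["m"], 9, np.array([-1.0]), 0.1, 1, [1.0], 11
        )
        t_b[0].organism = "org1"
        e_b[0].species = "org1"
        uni = fit_universal_model([(t_a[0], e_a[0]), (t_b[0], e_b[0])],
                                  folds=4, seed=0)
        spec_a = fit_organism_model(t_a[0], e_a[0], folds=4, seed=0)
        spec_b = fit_organism_model(t_b[0], e_b[0], folds=4, seed=0)
        mean_specific = (spec_a.cv_accuracy + spec_b.cv_accuracy) / 2
        assert uni.cv_accuracy < mean_specific

    def test_mark_set_mismatch_is_an_error(self):
        t_a, e_a, _ = simulate_chromatin(50, ["m"], 5, np.array([1.0]),
                                         0.0, 1, [1.0], 1)
        t_b, e_b, _ = simulate_chromatin(50, ["x"], 5, np.array([1.0]),
                                         0.0, 1, [1.0], 1)
        t_b[0].organism = "org1"
        with pytest.raises(ValidationError):
            fit_universal_model([(t_a[0], e_a[0]), (t_b[0], e_b[0])])


class TestPredict:
    def test_training_predictions_are_perfect_without_noise(self):
        tensors, exprs, truth = simulate_chromatin(
            200, ["a", "b"], 9, np.array([0.5, 0.5]), 0.0, 1, [1.0], 12
        )
        peak = dict(zip(truth.marks, truth.peak_bins))
        fit = fit_organism_model(tensors[0], exprs[0], folds=4, seed=0,
                                 best_bins=peak)
        _, r = predict_expression(fit, tensors[0], exprs[0])
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_constant_predictions_report_zero_with_warning(self):
        tensors, exprs, _ = simulate_chromatin(
            100, ["a"], 5, np.array([0.5]), 0.2, 1, [1.0], 13
        )
        fit = fit_organism_model(tensors[0], exprs[0], folds=4, seed=0)
        fit.coef = np.zeros_like(fit.coef)
        with pytest.warns(UserWarning, match="constant"):
            _, r = predict_expression(fit, tensors[0], exprs[0])
        assert r == 0.0

    def test_universal_predict_requires_known_organism(self):
        tensors, exprs, _ = simulate_chromatin(
            100, ["a"], 5, np.array([0.5]), 0.1, 2, [1.0, 2.0], 14
        )
        uni = UniversalChromatinModel(list(zip(tensors, exprs))).fit(
            folds=3, seed=0
        )
        stranger = SignalTensor(
            organism="mystery", genes=tensors[0].genes, marks=tensors[0].marks,
            scheme=tensors[0].scheme, values=tensors[0].values,
        )
        with pytest.raises(ValidationError, match="mystery"):
            uni.predict(stranger)


class TestTfSubsetCurve:
    def test_full_subset_equals_full_model(self):
        tensors, exprs, _ = simulate_chromatin(
            300, ["t1", "t2", "t3"], 9, np.array([0.5, 0.3, 0.0]),
            0.3, 1, [1.0], 15,
        )
        curve = tf_subset_curve(tensors[0], exprs[0], [3], reps=1,
                                folds=4, seed=99)
        rng = np.random.default_rng(99)
        rng.choice(3, size=3, replace=False)
        full = fit_organism_model(tensors[0], exprs[0], folds=4,
                                  seed=int(rng.integers(2**31)))
        assert curve.loc[0, "mean_accuracy"] == pytest.approx(full.cv_accuracy)

    def test_curve_is_reproducible_and_validates_n(self):
        tensors, exprs, _ = simulate_chromatin(
            200, ["t1", "t2", "t3", "t4"], 9,
            np.array([0.5, 0.4, 0.0, 0.0]), 0.3, 1, [1.0], 16,
        )
        a = tf_subset_curve(tensors[0], exprs[0], [2, 4], reps=3, folds=3, seed=1)
        b = tf_subset_curve(tensors[0], exprs[0], [2, 4], reps=3, folds=3, seed=1)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValidationError):
            tf_subset_curve(tensors[0], exprs[0], [5], reps=1, folds=3, seed=1)
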