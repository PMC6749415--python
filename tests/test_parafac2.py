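"""PARAFAC2 fitting, triage, semiquantification and spectral matching."""

import numpy as np
import pytest

from metabopipe.datatypes import Interval, SpectrumRecord
from metabopipe.parafac2 import (
    classify_components,
    creatinine_normalize,
    deconvolve_tensor,
    extract_relative_concentrations,
    fit_parafac2,
    match_factors,
    match_spectrum,
    propose_intervals,
    read_intervals,
    select_rank,
    tucker_congruence,
    write_intervals,
)
from metabopipe.synthetic import make_dataset


def _slabs(ds):
    return [ds.tensor.data[k] for k in range(ds.tensor.n_samples)]


class TestFit:
    def test_noiseless_exact_recovery(self, exact_noiseless):
        # SVD start alone reaches the global optimum here; skip the random
        # restarts so the deep-tolerance run stays quick
        m = fit_parafac2(
            _slabs(exact_noiseless), 3, tol=1e-14, max_iter=20000, seed=0, n_starts=1
        )
        assert m.fit_percent > 99.99
        _, cc = match_factors(m.spectra, exact_noiseless.truth.spectra)
        _, cd = match_factors(m.scores, exact_noiseless.truth.scores)
        assert np.all(cc >= 0.99)
        assert np.all(cd >= 0.99)

    def test_rank1_scores_proportional_to_truth(self):
        ds = make_dataset(
            n_samples=8, n_rt=60, n_mz=30, R=1, mode="exact_parafac2",
            shift_max=2, noise_sd=0.0, effect_log2fc=0.0, seed=2,
        )
        m = fit_parafac2(_slabs(ds), 1, tol=1e-12, max_iter=2000)
        r = np.corrcoef(m.scores[:, 0], ds.truth.scores[:, 0])[0, 1]
        assert r > 0.9999

    def test_sse_monotone_nonincreasing(self, exact_noiseless):
        m = fit_parafac2(_slabs(exact_noiseless), 2, tol=0.0, max_iter=60)
        h = m.sse_history
        assert np.all(np.diff(h) <= 1e-9 * h[:-1])

    def test_cross_product_constraint_at_convergence(self, exact_noiseless):
        m = fit_parafac2(_slabs(exact_noiseless), 3, tol=1e-10, max_iter=2000)
        assert m.cross_product_residual() <= 1e-6

    def test_factors_nonnegative(self, exact_noiseless):
        m = fit_parafac2(_slabs(exact_noiseless), 3, tol=1e-8, max_iter=500)
        assert np.all(m.spectra >= 0)
        assert np.all(m.scores >= 0)

    def test_all_zero_interval_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_parafac2([np.zeros((10, 5))] * 3, 1)

    def test_nonconvergence_flagged_not_raised(self, exact_noiseless):
        m = fit_parafac2(_slabs(exact_noiseless), 3, tol=1e-16, max_iter=5)
        assert m.converged is False
        assert m.iterations_used == 5

    def test_deterministic_given_seed(self, exact_noiseless):
        a = fit_parafac2(_slabs(exact_noiseless), 2, max_iter=50, seed=3, n_starts=2)
        b = fit_parafac2(_slabs(exact_noiseless), 2, max_iter=50, seed=3, n_starts=2)
        np.testing.assert_array_equal(a.spectra, b.spectra)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestRankSelection:
    def test_two_component_interval_recommends_two(self):
        ds = make_dataset(
            n_samples=8, n_rt=60, n_mz=30, R=2, mode="exact_parafac2",
            shift_max=2, noise_sd=0.0, effect_log2fc=0.0, seed=4,
        )
        r, report = select_rank(_slabs(ds), R_max=4, tol=1e-10)
        assert r == 2
        fits = report["fit_percent"]
        assert fits[2] > 99.9
        # fit percent non-decreasing in R
        assert all(fits[i + 1] >= fits[i] - 1e-6 for i in range(1, 4))

    def test_pure_noise_recommends_one_flagged(self, rng):
        slabs = [rng.normal(size=(30, 20)) for _ in range(6)]
        r, report = select_rank(slabs, R_max=3)
        assert r == 1
        assert report["low_fit_flag"]

    def test_degenerate_threshold_always_one(self, exact_noiseless):
        r, _ = select_rank(_slabs(exact_noiseless), R_max=3, fit_gain_threshold=100.0)
        assert r == 1


class TestClassification:
    def _model_with(self, profiles, spectra, scores):
        from metabopipe.datatypes import Parafac2Model

        return Parafac2Model(
            rank=spectra.shape[1],
            spectra=spectra,
            scores=scores,
            elution=[profiles] * scores.shape[0],
            coupling=np.eye(spectra.shape[1]),
            sse_history=np.array([1.0]),
            fit_percent=99.0,
            iterations_used=1,
            converged=True,
        )

    def test_three_archetypes_labeled(self, rng):
        n_rt, n_mz, n_samp = 60, 40, 5
        t = np.arange(n_rt)
        flat = np.full(n_rt, 2.0)                       # constant offset
        gauss = np.exp(-0.5 * ((t - 30) / 3.0) ** 2)    # clean peak
        ragged = 0.5 + rng.random(n_rt)                 # multimodal wiggle
        profiles = np.column_stack([flat, gauss, ragged])
        sparse = np.zeros(n_mz)
        sparse[[5, 12, 20]] = [1.0, 0.5, 0.2]
        sparse /= np.linalg.norm(sparse)
        white = np.ones(n_mz) / np.sqrt(n_mz)
        spectra = np.column_stack([white * 0.9 + 0.1 / n_mz, sparse, white])
        scores = np.abs(rng.random((n_samp, 3))) + 0.5
        labels = classify_components(self._model_with(profiles, spectra, scores))
        assert labels[0].label == "baseline"
        assert labels[1].label == "compound"
        assert labels[2].label == "noise"

    def test_manual_override_wins(self, rng):
        t = np.arange(60)
        gauss = np.exp(-0.5 * ((t - 30) / 3.0) ** 2)[:, None]
        spec = np.zeros((40, 1))
        spec[4] = 1.0
        model = self._model_with(gauss, spec, np.ones((3, 1)))
        labels = classify_components(model, override={0: "noise"})
        assert labels[0].label == "noise"


class TestSemiquantification:
    def test_noiseless_linearity_per_compound(self, exact_noiseless):
        ds = exact_noiseless
        m = fit_parafac2(_slabs(ds), 3, tol=1e-12, max_iter=3000,
                         interval=Interval(0, ds.tensor.n_rt, "TMS"))
        labels = [[type(lb)("compound", lb.diagnostics) for lb in classify_components(m)]]
        table = extract_relative_concentrations(
            [m], labels, sample_ids=list(ds.tensor.sample_ids)
        )
        perm, _ = match_factors(m.scores, ds.truth.scores)
        for r in range(3):
            est = table.values.iloc[:, int(perm[r])].values
            r_corr = np.corrcoef(est, ds.truth.scores[:, r])[0, 1]
            assert r_corr >= 0.999

    def test_doubling_concentration_doubles_value(self):
        ds = make_dataset(
            n_samples=6, n_rt=60, n_mz=30, R=2, mode="exact_parafac2",
            shift_max=0, noise_sd=0.0, effect_log2fc=0.0, seed=8,
        )
        truth = ds.truth
        iv = Interval(0, 60, "TMS")

        def extracted(scores):
            data = [
                (truth.elution[k] * scores[k][None, :]) @ truth.spectra.T
                for k in range(6)
            ]
            m = fit_parafac2(data, 2, tol=1e-13, max_iter=4000, interval=iv)
            labs = [[type(lb)("compound", {}) for lb in classify_components(m)]]
            t = extract_relative_concentrations([m], labs)
            perm, _ = match_factors(m.scores, scores)
            return t.values.iloc[:, int(perm[0])].values

        base = extracted(truth.scores)
        doubled_scores = truth.scores.copy()
        doubled_scores[2, 0] *= 2.0
        doubled = extracted(doubled_scores)
        ratio = doubled[2] / base[2]
        assert abs(ratio - 2.0) < 0.002

    def test_baseline_component_excluded(self, exact_noiseless):
        m = fit_parafac2(_slabs(exact_noiseless), 3, max_iter=200,
                         interval=Interval(0, 80, "TMS"))
        from metabopipe.datatypes import ComponentLabel

        labels = [[ComponentLabel("baseline"), ComponentLabel("compound"),
                   ComponentLabel("noise")]]
        table = extract_relative_concentrations([m], labels)
        assert table.values.shape[1] == 1


class TestCreatinine:
    def _table(self, creat):
        import pandas as pd

        from metabopipe.datatypes import FeatureTable

        values = pd.DataFrame(
            np.ones((3, 2)), index=list("abc"), columns=["x", "y"]
        )
        return FeatureTable(
            values=values,
            provenance=pd.DataFrame(index=values.columns),
            creatinine=pd.Series(creat, index=values.index),
        )

    def test_unit_creatinine_no_change(self):
        t = creatinine_normalize(self._table([1.0, 1.0, 1.0]))
        assert np.all(t.values.values == 1.0)
        assert t.normalized

    def test_doubled_creatinine_halves_row(self):
        t = creatinine_normalize(self._table([1.0, 2.0, 1.0]))
        np.testing.assert_allclose(t.values.loc["b"].values, 0.5)

    def test_zero_creatinine_names_sample(self):
        with pytest.raises(ValueError, match="b"):
            creatinine_normalize(self._table([1.0, 0.0, 1.0]))


class TestSpectralMatch:
    def test_self_match_is_999(self):
        lib = [
            SpectrumRecord("a", np.array([50.0, 70.0]), np.array([100.0, 50.0])),
            SpectrumRecord("b", np.array([51.0, 80.0]), np.array([10.0, 90.0])),
        ]
        ranked = match_spectrum(lib[0], lib)
        assert ranked[0][0] == "a"
        assert np.isclose(ranked[0][1], 999.0)

    def test_disjoint_support_scores_zero(self):
        q = SpectrumRecord("q", np.array([50.0, 51.0]), np.array([1.0, 2.0]))
        lib = [SpectrumRecord("far", np.array([200.0, 201.0]), np.array([3.0, 4.0]))]
        assert match_spectrum(q, lib)[0][1] == 0.0

    def test_hand_computed_half_overlap(self):
        # q: {50:4, 60:9}; l: {60:1, 70:16}
        # sqrt-weighted dot = sqrt(9*1) = 3; factor = 999*3^2/((4+9)*(1+16))
        q = SpectrumRecord("q", np.array([50.0, 60.0]), np.array([4.0, 9.0]))
        lib = [SpectrumRecord("l", np.array([60.0, 70.0]), np.array([1.0, 16.0]))]
        expected = 999.0 * 9.0 / (13.0 * 17.0)
        assert np.isclose(match_spectrum(q, lib)[0][1], expected, atol=1e-10)

    def test_empty_library_rejected(self):
        q = SpectrumRecord("q", np.array([50.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            match_spectrum(q, [])


class TestIntervals:
    def test_interval_csv_round_trip(self, tmp_path):
        ivs = [Interval(0, 50, "TMS", 3), Interval(50, 120, "TFA", None)]
        path = tmp_path / "iv.csv"
        write_intervals(ivs, path)
        back = read_intervals(path)
        assert back == ivs

    def test_propose_intervals_cover_peaks(self, exact_noiseless):
        ivs = propose_intervals(exact_noiseless.tensor)
        assert len(ivs) >= 1
        assert all(0 <= iv.start < iv.stop <= exact_noiseless.tensor.n_rt for iv in ivs)
        starts = [iv.start for iv in ivs]
        assert starts == sorted(starts)

    def test_deconvolve_tensor_end_to_end(self, exact_noiseless):
        ivs = [Interval(0, exact_noiseless.tensor.n_rt, "TMS", 3)]
        table, models = deconvolve_tensor(
            exact_noiseless.tensor, ivs,
            creatinine=exact_noiseless.creatinine, max_iter=500,
        )
        assert len(models) == 1
        assert table.values.shape[0] == exact_noiseless.tensor.n_samples
        assert (table.values.values >= 0).all()


def test_tucker_congruence_bounds(rng):
    a = rng.normal(size=30)
    assert np.isclose(tucker_congruence(a, a), 1.0)
    assert np.isclose(tucker_congruence(a, -a), 1.0)  # sign-insensitive
    b = np.zeros(30)
    assert tucker_congruence(a, b) == 0.0
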