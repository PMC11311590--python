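import numpy as np
import pytest
from scipy.optimize import brentq

from hemekin.mcd import (
    BasisSet,
    TwoStateUnmixingModel,
    asymmetry_score,
    find_isosbestic,
    normalize_to_concentration,
    reconstruct_complex_basis,
    unmix,
)
from hemekin.spectra import SpectralSeries, Spectrum
from hemekin.synthetic import (
    complex_basis_bands,
    free_basis_bands,
    gen_two_state_mcd_series,
    mcd_grid,
)


def eval_bands(bands, wl):
    return sum(b.evaluate(wl) for b in bands)


def mix(f, truth):
    return Spectrum(
        truth.basis_complex.wavelengths,
        f * truth.basis_complex.values + (1 - f) * truth.basis_free.values,
    )


class TestNormalizeToConcentration:
    def test_unit_concentration_is_identity(self, noiseless_mcd):
        series, _ = noiseless_mcd
        out = normalize_to_concentration(series, 1.0)
        assert np.allclose(out.values_matrix, series.values_matrix)

    def test_scaling_factor(self, noiseless_mcd):
        series, _ = noiseless_mcd
        out = normalize_to_concentration(series, 25.0)
        assert np.allclose(out.values_matrix, series.values_matrix * 0.04)

    def test_fractions_invariant_to_joint_scaling(self, noiseless_mcd, true_basis):
        series, truth = noiseless_mcd
        base = unmix(series, true_basis)
        scaled_basis = BasisSet(
            true_basis.basis_complex.scaled(0.04),
            true_basis.basis_free.scaled(0.04),
            true_basis.zero_cross_nm,
            true_basis.f0,
            true_basis.asymmetry_score,
        )
        scaled = unmix(normalize_to_concentration(series, 25.0), scaled_basis)
        assert np.allclose(scaled.fraction_complex, base.fraction_complex)

    def test_nonpositive_concentration_rejected(self, noiseless_mcd):
        with pytest.raises(ValueError):
            normalize_to_concentration(noiseless_mcd[0], 0.0)


class TestReconstructComplexBasis:
    def test_pure_antisymmetric_input_recovered_exactly(self, noiseless_mcd):
        _, truth = noiseless_mcd
        basis = reconstruct_complex_basis(
            truth.basis_complex, truth.basis_free
        )
        assert basis.f0 == pytest.approx(1.0, abs=1e-6)
        assert np.max(
            np.abs(basis.basis_complex.values - truth.basis_complex.values)
        ) < 1e-10

    def test_95_5_mixture_recovered(self, noiseless_mcd):
        _, truth = noiseless_mcd
        basis = reconstruct_complex_basis(mix(0.95, truth), truth.basis_free)
        assert basis.f0 == pytest.approx(0.95, abs=0.01)
        peak = np.max(np.abs(truth.basis_complex.values))
        rms = np.sqrt(
            np.mean(
                (basis.basis_complex.values - truth.basis_complex.values) ** 2
            )
        )
        assert rms <= 0.01 * peak

    def test_recovered_extrema_at_550_and_555(self, noiseless_mcd):
        _, truth = noiseless_mcd
        basis = reconstruct_complex_basis(mix(0.9, truth), truth.basis_free)
        wl = basis.basis_complex.wavelengths
        vals = basis.basis_complex.values
        grid_step = wl[1] - wl[0]
        assert abs(wl[np.argmax(vals)] - 550.0) <= grid_step
        assert abs(wl[np.argmin(vals)] - 555.0) <= grid_step

    def test_asymmetry_not_worse_than_input(self, noiseless_mcd):
        _, truth = noiseless_mcd
        first = mix(0.9, truth)
        basis = reconstruct_complex_basis(first, truth.basis_free)
        assert basis.asymmetry_score <= asymmetry_score(first) + 1e-12

    def test_flat_free_spectrum_rejected(self, noiseless_mcd):
        _, truth = noiseless_mcd
        wl = truth.basis_free.wavelengths
        flat = Spectrum(wl, np.zeros_like(wl))
        with pytest.raises(ValueError, match="flat"):
            reconstruct_complex_basis(truth.basis_complex, flat)

    def test_no_zero_crossing_rejected(self):
        wl = mcd_grid()
        gauss = Spectrum(wl, np.exp(-((wl - 550) ** 2) / 8.0) + 0.5)
        with pytest.raises(ValueError, match="zero crossing"):
            asymmetry_score(gauss)


class TestUnmix:
    def test_even_mixture_exact(self, noiseless_mcd, true_basis):
        _, truth = noiseless_mcd
        series = SpectralSeries((mix(0.5, truth),), [0.0])
        res = unmix(series, true_basis)
        assert res.fraction_complex[0] == pytest.approx(0.5, abs=1e-12)

    def test_pure_endpoints(self, noiseless_mcd, true_basis):
        _, truth = noiseless_mcd
        series = SpectralSeries(
            (
                Spectrum(
                    truth.basis_complex.wavelengths,
                    truth.basis_complex.values,
                    time_min=0.0,
                ),
                Spectrum(
                    truth.basis_free.wavelengths,
                    truth.basis_free.values,
                    time_min=1.0,
                ),
            )
        )
        res = unmix(series, true_basis)
        assert res.fraction_complex[0] == pytest.approx(1.0, abs=1e-12)
        assert res.fraction_complex[1] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_series_exact(self, noiseless_mcd, true_basis):
        series, truth = noiseless_mcd
        res = unmix(series, true_basis)
        assert np.max(
            np.abs(res.fraction_complex - truth.true_fractions)
        ) < 1e-10

    def test_noisy_recovery_snr50(self, true_basis):
        peak = float(np.max(np.abs(true_basis.basis_complex.values)))
        series, truth = gen_two_state_mcd_series(noise_sd=peak / 50, seed=7)
        res = unmix(series, true_basis)
        assert np.max(
            np.abs(res.fraction_complex - truth.true_fractions)
        ) <= 0.02

    def test_error_decreases_with_snr(self, true_basis):
        peak = float(np.max(np.abs(true_basis.basis_complex.values)))
        errs = []
        for snr in (10, 50, 250):
            series, truth = gen_two_state_mcd_series(
                noise_sd=peak / snr, seed=19
            )
            res = unmix(series, true_basis)
            errs.append(
                float(np.max(np.abs(res.fraction_complex - truth.true_fractions)))
            )
        assert errs[0] > errs[1] > errs[2]

    def test_closed_form_matches_grid_search_oracle(self, true_basis, rng):
        """1-D grid search of the residual at 1e-4 resolution agrees with
        the closed-form projection on random noisy mixtures."""
        b_c = true_basis.basis_complex.values
        b_f = true_basis.basis_free.values
        wl = true_basis.basis_complex.wavelengths
        fs = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        recon = np.outer(fs, b_c) + np.outer(1 - fs, b_f)
        for _ in range(20):
            f_true = rng.uniform()
            s = f_true * b_c + (1 - f_true) * b_f + rng.normal(0, 0.01, b_c.size)
            f_grid = fs[np.argmin(((s[None, :] - recon) ** 2).sum(axis=1))]
            res = unmix(
                SpectralSeries((Spectrum(wl, s),), [0.0]), true_basis
            )
            assert abs(res.fraction_raw[0] - f_grid) <= 1e-4

    def test_residual_orthogonal_to_basis_difference(self, true_basis, rng):
        """Least-squares residual (pre-clipping) is orthogonal to B_c-B_f."""
        b_c = true_basis.basis_complex.values
        b_f = true_basis.basis_free.values
        wl = true_basis.basis_complex.wavelengths
        s = 0.6 * b_c + 0.4 * b_f + rng.normal(0, 0.05, b_c.size)
        res = unmix(SpectralSeries((Spectrum(wl, s),), [0.0]), true_basis)
        f = res.fraction_raw[0]
        resid = s - (f * b_c + (1 - f) * b_f)
        d = b_c - b_f
        assert abs(resid @ d) < 1e-10 * np.linalg.norm(d) * np.linalg.norm(s)

    def test_fractions_clipped_to_unit_interval(self, true_basis, rng):
        b_c = true_basis.basis_complex.values
        wl = true_basis.basis_complex.wavelengths
        s = 2.0 * b_c  # outside the two-state simplex
        res = unmix(SpectralSeries((Spectrum(wl, s),), [0.0]), true_basis)
        assert res.fraction_complex[0] == 1.0
        assert res.fraction_raw[0] > 1.0

    def test_identical_bases_rejected(self, true_basis):
        bad = BasisSet(
            true_basis.basis_complex,
            true_basis.basis_complex,
            552.5,
            1.0,
            0.0,
        )
        series, _ = gen_two_state_mcd_series(seed=0)
        with pytest.raises(ValueError, match="indistinguishable"):
            unmix(series, bad)


class TestIsosbestic:
    def test_noiseless_series_crossings_match_basis_roots(self, noiseless_mcd):
        """Isosbestic wavelengths are the roots of B_c - B_f: verify
        against an independent analytic root-find on the band models."""
        series, _ = noiseless_mcd
        wl = series.wavelengths
        bc_bands = complex_basis_bands()
        bf_bands = free_basis_bands()

        def diff(x):
            return eval_bands(bc_bands, np.array([x]))[0] - eval_bands(
                bf_bands, np.array([x])
            )[0]

        roots = []
        xs = np.linspace(535.0, 560.0, 2501)
        ys = np.array([diff(x) for x in xs])
        for i in np.nonzero(np.diff(np.sign(ys)) != 0)[0]:
            roots.append(brentq(diff, xs[i], xs[i + 1]))
        found = find_isosbestic(series)
        assert len(found) == len(roots) == 2
        step = wl[1] - wl[0]
        for f, r in zip(sorted(found), sorted(roots)):
            assert abs(f - r) <= step / 2

    def test_crossings_lie_between_band_extrema(self, noiseless_mcd):
        series, _ = noiseless_mcd
        low, high = sorted(find_isosbestic(series))
        assert 545.0 < low < 550.0
        assert 550.0 < high < 555.0

    def test_degenerate_series_returns_empty_with_warning(self):
        wl = mcd_grid()
        vals = np.sin((wl - 530) / 5.0)
        series = SpectralSeries.from_matrix(
            wl, np.tile(vals, (4, 1)), [0, 1, 2, 3]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            assert find_isosbestic(series) == []

    def test_needs_three_spectra(self, noiseless_mcd):
        series, _ = noiseless_mcd
        short = SpectralSeries(series.spectra[:2], series.times_min[:2])
        with pytest.raises(ValueError):
            find_isosbestic(short)


class TestTwoStateUnmixingModel:
    def test_monotone_percent_on_decay_series(self):
        series, _ = gen_two_state_mcd_series(noise_sd=0.0, seed=2)
        results = TwoStateUnmixingModel(series).fit()
        assert np.all(np.diff(results.percent_complex) <= 1e-9)

    def test_summary_and_frame(self, noiseless_mcd):
        series, _ = noiseless_mcd
        results = TwoStateUnmixingModel(series, cytc_uM=25.0).fit()
        frame = results.to_frame()
        assert list(frame.columns) == [
            "time_min", "percent_complex", "residual_rms",
        ]
        assert "isosbestic" in results.summary()

    def test_decay_fit_recovers_rate(self):
        series, truth = gen_two_state_mcd_series(noise_sd=0.0, seed=2)
        results = TwoStateUnmixingModel(series).fit()
        fit = results.decay_fit()
        assert fit.converged
        # fractions are measured against the slightly contaminated
        # end-of-run free spectrum, leaving the rate constant intact
        assert fit.k_per_min == pytest.approx(
            truth.true_rate_constant_per_min, rel=0.02
        )
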