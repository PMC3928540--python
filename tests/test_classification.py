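import math

import numpy as np
import pytest

from revcor.archive import CELLS, RunArchive, TrialRecord
from revcor.classification import (EmptyCellError, bootstrap_profiles,
                                   classification_image, infill_inducers,
                                   null_band, peak_frequency, radial_average,
                                   radial_classification_profile,
                                   smooth_image, spectral_profile)
from revcor.radial import RadialBinning
from revcor.stimuli import (DisplaySpec, pixels_to_degrees, render_stimulus,
                            spec_for, truncated_variance_factor)


def make_label_archive(n_trials, seed, responses=None, window=64, sigma2=0.16,
                       store_fields=True):
    """Archive of pure truncated noise with prescribed/random S-R labels."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((window, window), dtype=bool)
    arch = RunArchive("none", window, sigma2, seed, mask,
                      store_fields=store_fields, n_bins=window // 2 - 1)
    sd = math.sqrt(sigma2)
    for t in range(n_trials):
        noise = rng.normal(0, sd, (window, window))
        bad = np.abs(noise) > 2 * sd
        while bad.any():
            noise[bad] = rng.normal(0, sd, int(bad.sum()))
            bad = np.abs(noise) > 2 * sd
        present = bool(t % 2)
        response = (bool(responses[t]) if responses is not None
                    else bool(rng.random() < 0.5))
        arch.add_trial(TrialRecord(t, "none", present, 1.0, t, response,
                                   response == present), noise)
    return arch


class TestClassificationImage:
    def test_random_responses_give_chance_level_weights(self):
        arch = make_label_archive(800, seed=1)
        ci = classification_image(arch.records, arch)
        # analytic per-pixel sd of the 4-cell combination
        sigma_eff2 = 0.16 * truncated_variance_factor()
        per_cell = [arch.cell_counts[c] for c in CELLS]
        sd = math.sqrt(sum(sigma_eff2 / n for n in per_cell))
        assert np.abs(ci.weights).max() < 6 * sd

    def test_ideal_weights_concentrate_in_dot(self, run_ideal_small_10k):
        prof = radial_classification_profile(run_ideal_small_10k.records,
                                             run_ideal_small_10k)
        center = prof.values[:18].mean()   # inside the 45-px dot
        outside = np.abs(prof.values[30:]).mean()
        assert center < 0                  # dark target -> negative weights
        assert abs(center) > 10 * outside

    def test_empty_cell_error_names_cell(self):
        records = [TrialRecord(t, "none", True, 1.0, t, True, True)
                   for t in range(8)]
        arch = make_label_archive(8, seed=2, responses=[1] * 8)
        with pytest.raises(EmptyCellError, match="stimulus-absent"):
            classification_image(records, arch)

    def test_cell_sum_and_field_routes_agree(self):
        arch = make_label_archive(60, seed=3)
        own = classification_image(arch.records, arch)
        # force the per-field route via a reordered (but identical) list
        shuffled = list(arch.records)
        shuffled[0], shuffled[1] = shuffled[1], shuffled[0]
        other = classification_image(shuffled, arch)
        assert np.allclose(own.weights, other.weights, atol=1e-12)

    def test_pooled_equals_concatenated(self):
        # cell-count-weighted combination across sessions == single pass
        a = make_label_archive(40, seed=4)
        b = make_label_archive(72, seed=5)
        merged = RunArchive("none", 64, 0.16, 0, np.zeros((64, 64), bool),
                            store_fields=True, n_bins=31)
        t = 0
        for arch in (a, b):
            for r in arch.records:
                merged.add_trial(
                    TrialRecord(t, r.condition, r.present, r.energy, t,
                                r.response, r.correct),
                    arch.noise_field(r.noise_ref))
                t += 1
        # identity: pooled cell means are count-weighted session cell means
        for cell in CELLS:
            na, nb = a.cell_counts[cell], b.cell_counts[cell]
            ma = a.cell_sums[cell] / na
            mb = b.cell_sums[cell] / nb
            mm = merged.cell_sums[cell] / merged.cell_counts[cell]
            assert np.allclose(mm, (na * ma + nb * mb) / (na + nb), atol=1e-12)
        pooled = classification_image(merged.records, merged)
        combo = np.zeros_like(pooled.weights)
        for sign, resp in ((1.0, True), (-1.0, False)):
            for pres in (False, True):
                cell = (pres, resp)
                na, nb = a.cell_counts[cell], b.cell_counts[cell]
                combo += sign * (a.cell_sums[cell] + b.cell_sums[cell]) / (na + nb)
        assert np.allclose(pooled.weights, combo, atol=1e-12)

    def test_missing_fields_is_loud(self, mini_archive):
        responses = [(t // 2) % 2 for t in range(16)]
        arch = make_label_archive(16, seed=6, responses=responses,
                                  store_fields=False)
        subset = list(arch.records)[:12]
        with pytest.raises(Exception, match="noise"):
            classification_image(subset, arch)


class TestSmoothing:
    def test_constant_unchanged(self):
        img = np.full((30, 30), 3.7)
        assert np.allclose(smooth_image(img, 7), img, atol=1e-12)

    def test_impulse_plateau(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = smooth_image(img, 7)
        assert np.allclose(out[12:19, 12:19], 1 / 49, atol=1e-12)
        assert out[15, 20] == 0.0

    def test_noise_variance_reduction(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(400, 400))
        out = smooth_image(img, 7)
        interior = out[10:-10, 10:-10]
        assert interior.var() == pytest.approx(1 / 49, rel=0.10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth_image(np.zeros((8, 8)), 4)


class TestInfill:
    def test_empty_mask_identity(self):
        arch = make_label_archive(16, seed=8)
        ci = classification_image(arch.records, arch)
        out = infill_inducers(ci, rng=0)
        assert np.array_equal(out.weights, ci.weights)

    def test_masked_pixels_randomized_unmasked_untouched(self, display):
        mask = render_stimulus(spec_for("small_inducers"), display,
                               False).inducer_mask
        arch = make_label_archive(16, seed=9, window=200)
        ci = classification_image(arch.records, arch)
        ci.inducer_mask = mask
        out = infill_inducers(ci, rng=1)
        assert np.array_equal(out.weights[~mask], ci.weights[~mask])
        filled = out.weights[mask]
        assert np.unique(filled).size == filled.size  # no constant footprint


class TestRadialAverage:
    def test_constant_image(self):
        prof = radial_average(np.full((200, 200), 2.5))
        assert prof.values == pytest.approx(np.full(99, 2.5))
        assert len(prof.values) == 99

    def test_gaussian_bump_matches_generator(self):
        n = 200
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - c, yy - c)
        img = np.exp(-r ** 2 / (2 * 20.0 ** 2))
        prof = radial_average(img)
        expected = np.exp(-prof.radii.astype(float) ** 2 / (2 * 20.0 ** 2))
        assert np.abs(prof.values - expected).max() < 0.02  # 2% of unit peak

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        img = rng.normal(size=(200, 200))
        a = radial_average(img)
        b = radial_average(np.rot90(img))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_profile_matches_image_route(self, mini_archive):
        via_vectors = radial_classification_profile(mini_archive.records,
                                                    mini_archive)
        ci = classification_image(mini_archive.records, mini_archive)
        via_image = radial_average(ci)
        assert np.allclose(via_vectors.values, via_image.values, atol=1e-12)

    def test_empty_bin_error(self):
        with pytest.raises(ValueError, match="bin"):
            RadialBinning(10, n_bins=99)


class TestSpectralProfile:
    def test_constant_all_energy_at_dc(self, display):
        prof = spectral_profile(np.full((200, 200), 1.3), display)
        assert prof.values[0] > 0
        assert prof.values[1:].max() < prof.values[0] * 1e-12

    def test_grating_peak_bin(self, display):
        n = 200
        pitch = pixels_to_degrees(1.0, display)
        k = round(6.0 * n * pitch)  # grid frequency nearest 6 c/deg
        x = np.arange(n)
        img = np.cos(2 * np.pi * k * x / n)[None, :].repeat(n, axis=0)
        prof = spectral_profile(img, display)
        peak = peak_frequency(prof, exclude_dc=True)
        assert peak == pytest.approx(k / (n * pitch))
        assert abs(peak - 6.0) < 1.0 / (n * pitch)

    def test_parseval(self, display):
        # spectrum confined to kept annuli: sum of binned power == pixel power
        n = 128
        x = np.arange(n)
        img = (0.7 * np.cos(2 * np.pi * 5 * x / n)[None, :].repeat(n, axis=0)
               + 0.2 * np.sin(2 * np.pi * 9 * x / n)[:, None].repeat(n, axis=1)
               + 0.1)
        prof = spectral_profile(img, display)
        total = float((prof.values * prof.counts).sum())
        assert total == pytest.approx(float((img ** 2).sum()), rel=1e-8)

    def test_nyquist_axis(self, display):
        prof = spectral_profile(np.zeros((200, 200)), display)
        pitch = pixels_to_degrees(1.0, display)
        assert prof.frequencies[0] == 0.0
        assert prof.frequencies[-1] == pytest.approx(1 / (2 * pitch))

    def test_non_square_rejected(self, display):
        with pytest.raises(ValueError):
            spectral_profile(np.zeros((8, 16)), display)


class TestPeakFrequency:
    def test_scale_invariant(self, display):
        rng = np.random.default_rng(11)
        prof = spectral_profile(rng.normal(size=(64, 64)), display)
        a = peak_frequency(prof)
        prof.values = prof.values * 7.3
        assert peak_frequency(prof) == a

    def test_monotone_profile_gives_first_non_dc_bin(self, display):
        from revcor.classification import SpectralProfile
        prof = SpectralProfile(np.arange(10, dtype=float),
                               np.linspace(5.0, 0.5, 10),
                               np.ones(10, dtype=int))
        assert peak_frequency(prof, exclude_dc=True) == 1.0

    def test_tie_error(self):
        from revcor.classification import SpectralProfile
        prof = SpectralProfile(np.arange(5, dtype=float), np.ones(5),
                               np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="tie"):
            peak_frequency(prof)


class TestBootstrapProfiles:
    def test_single_replicate_zero_sd(self):
        arch = make_label_archive(64, seed=12)
        band = bootstrap_profiles(arch.records, arch, n=1, seed=0)
        assert np.allclose(band.sd, 0.0)

    def test_seeded_reproducibility(self):
        arch = make_label_archive(64, seed=13)
        a = bootstrap_profiles(arch.records, arch, n=20, seed=3)
        b = bootstrap_profiles(arch.records, arch, n=20, seed=3)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.sd, b.sd)

    def test_band_shrinks_with_trials(self):
        small = make_label_archive(400, seed=14)
        big = make_label_archive(1600, seed=15)
        sd_small = bootstrap_profiles(small.records, small, n=80,
                                      seed=4).sd.mean()
        sd_big = bootstrap_profiles(big.records, big, n=80, seed=4).sd.mean()
        assert 1.4 < sd_small / sd_big < 2.9  # ~sqrt(4) = 2


class TestNullBand:
    def test_mean_near_zero(self, run_ideal_small_1k):
        band = null_band(run_ideal_small_1k.records, run_ideal_small_1k,
                         n=40, seed=5)
        assert np.all(np.abs(band.mean) < 0.5 * band.sd)

    def test_sd_matches_analytic_iid_prediction(self, run_ideal_small_1k):
        arch = run_ideal_small_1k
        band = null_band(arch.records, arch, n=60, seed=6)
        sigma_eff2 = arch.sigma2 * truncated_variance_factor()
        counts = arch.binning.counts
        var = np.zeros(99)
        for cell in CELLS:
            var += sigma_eff2 / (counts * arch.cell_counts[cell])
        predicted = np.sqrt(var)
        ratio = band.sd / predicted
        # mean ratio pins the closed form; per-bin spread is replicate noise
        assert 0.9 < ratio.mean() < 1.1
        assert np.all((ratio > 0.7) & (ratio < 1.3))

    def test_ideal_center_outside_far_field_inside(self, run_ideal_small_10k):
        band = null_band(run_ideal_small_10k.records, run_ideal_small_10k,
                         n=40, seed=7)
        prof = radial_classification_profile(run_ideal_small_10k.records,
                                             run_ideal_small_10k)
        center = slice(0, 18)
        assert np.all(prof.values[center] < band.lower[center])
        far = slice(60, 99)
        inside = ((prof.values[far] >= band.lower[far])
                  & (prof.values[far] <= band.upper[far]))
        assert inside.mean() >= 0.9
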