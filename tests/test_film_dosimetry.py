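"""Film pipeline: channel handling, calibration, filtering, dose maps, OFs."""

import numpy as np
import pytest

from smallfield.film_dosimetry import (
    CalibrationCurve,
    FilmScan,
    dose_map,
    film_output_factor,
    fit_calibration,
    median_filter,
    net_response,
    read_film_tiff,
    red_channel,
    write_film_tiff,
)
from smallfield.synthetic_data import FilmModel, make_film_set


def make_scan(red, green=None, blue=None, dpi=600.0):
    red = np.asarray(red, dtype=np.uint16)
    green = red if green is None else np.full_like(red, green)
    blue = red if blue is None else np.full_like(red, blue)
    return FilmScan(pixels=np.stack([red, green, blue], axis=-1), dpi=dpi)


@pytest.fixture(scope="module")
def calibration():
    """Calibration fitted from ten synthetic uniform films, 0-2 Gy."""
    doses = np.linspace(0.0, 2.0, 10)
    responses = []
    for i, d in enumerate(doses):
        films, unexp, _ = make_film_set(d, n_repeats=1, seed=200 + i,
                                        shape=(40, 40))
        nod = net_response(red_channel(films[0]), red_channel(unexp))
        responses.append(np.median(median_filter(nod, 5)))
    return fit_calibration(doses, np.array(responses), batch_id="synthetic")


class TestChannels:
    def test_red_channel_identity(self):
        red = np.full((8, 8), 1234)
        scan = make_scan(red, green=10, blue=20)
        assert np.array_equal(red_channel(scan), red)

    def test_channel_order(self):
        scan = make_scan(np.full((4, 4), 100), green=200, blue=300)
        assert red_channel(scan)[0, 0] == 100

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            FilmScan(pixels=np.zeros((4, 4, 2), dtype=np.uint16), dpi=600)

    def test_tiff_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        scan = make_scan(rng.integers(100, 60000, (16, 16)))
        path = tmp_path / "film.tiff"
        write_film_tiff(path, scan)
        back = read_film_tiff(path)
        assert np.array_equal(back.pixels, scan.pixels)
        assert back.dpi == pytest.approx(600.0)


class TestNetResponse:
    def test_equal_images_give_zero(self):
        img = np.full((5, 5), 30000.0)
        assert np.allclose(net_response(img, img), 0.0)

    def test_halved_intensity_gives_log10_two(self):
        u = np.full((5, 5), 40000.0)
        assert np.allclose(net_response(u / 2, u), np.log10(2.0))

    def test_nonpositive_intensity_rejected(self):
        u = np.full((3, 3), 100.0)
        with pytest.raises(ValueError, match="positive"):
            net_response(np.zeros((3, 3)), u)

    def test_generator_forward_model_inverts(self):
        model = FilmModel(pixel_noise=0.0)
        films, unexp, _ = make_film_set(1.0, model=model, n_repeats=1,
                                        seed=0, shape=(10, 10))
        nod = net_response(red_channel(films[0]), red_channel(unexp))
        assert np.allclose(model.dose_for(nod), 1.0, atol=5e-3)


class TestCalibration:
    def test_exact_cubic_recovered(self):
        coefs = np.array([0.0, 2.0, 1.0, 4.0])
        resp = np.linspace(0.01, 0.5, 10)
        doses = np.polynomial.Polynomial(coefs)(resp)
        cal = fit_calibration(doses, resp)
        assert np.allclose(cal.coefficients, coefs, atol=1e-10)

    def test_noisy_calibration_dose_error_bounded(self, calibration):
        """Full synthetic calibration: dose error under 2% of 2 Gy."""
        model = FilmModel()
        grid = np.linspace(calibration.response_range[0] + 1e-6,
                           calibration.response_range[1], 100)
        err = np.abs(calibration(grid) - model.dose_for(grid))
        assert err.max() <= 0.04

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_calibration([0.0, 1.0, 2.0], [0.0, 0.2, 0.4])

    def test_duplicate_responses_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0, 0.5, 1.0, 1.5, 2.0],
                            [0.0, 0.1, 0.1, 0.3, 0.4])

    def test_nonmonotone_fit_rejected(self):
        resp = np.linspace(0, 1, 8)
        doses = np.array([0.0, 0.5, 1.0, 0.6, 0.4, 1.2, 1.8, 2.0])
        with pytest.raises(ValueError, match="monoton|calibration"):
            fit_calibration(doses, resp)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            CalibrationCurve(coefficients=np.array([0.0, -1.0, 0.0, 0.0]),
                             response_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="zero response"):
            CalibrationCurve(coefficients=np.array([0.5, 1.0, 0.0, 0.0]),
                             response_range=(0.0, 0.5))


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 7.0)
        assert np.array_equal(median_filter(img, 3), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert median_filter(img, 3)[4, 4] == 0.0

    def test_matches_bruteforce_sliding_window(self):
        rng = np.random.default_rng(21)
        img = rng.uniform(0, 1, (20, 20))
        got = median_filter(img, 3)
        padded = np.pad(img, 1, mode="symmetric")  # scipy's "reflect"
        brute = np.empty_like(img)
        for i in range(20):
            for j in range(20):
                brute[i, j] = np.median(padded[i:i + 3, j:j + 3])
        assert np.array_equal(got, brute)

    def test_idempotent_on_piecewise_constant(self):
        img = np.zeros((12, 12))
        img[:, 6:] = 1.0
        once = median_filter(img, 3)
        assert np.array_equal(median_filter(once, 3), once)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter(np.zeros((5, 5)), 4)


class TestDoseMap:
    def test_spacing_from_dpi(self, calibration):
        films, unexp, truth = make_film_set(1.0, n_repeats=1, seed=31,
                                            shape=(20, 20))
        _, spacing = dose_map(films[0], unexp, calibration)
        assert spacing == pytest.approx(25.4 / 600.0, abs=1e-4)
        assert spacing == pytest.approx(0.0423, abs=5e-4)

    def test_flat_two_gray_film_recovered(self, calibration):
        films, unexp, _ = make_film_set(2.0, n_repeats=1, seed=32,
                                        shape=(30, 30))
        dose, _ = dose_map(films[0], unexp, calibration)
        assert np.median(dose) == pytest.approx(2.0, abs=0.04)

    def test_unexposed_film_reads_near_zero(self, calibration):
        films, unexp, _ = make_film_set(0.0, n_repeats=2, seed=33,
                                        shape=(30, 30))
        dose, _ = dose_map(films[0], films[1], calibration)
        assert abs(np.median(dose)) < 0.05

    def test_out_of_range_pixels_rejected(self, calibration):
        model = FilmModel()
        u = np.full((10, 10), model.unexposed_intensity)
        # darker than any calibrated response
        exposed = make_scan(np.full((10, 10), 100))
        unexp = make_scan(u)
        with pytest.raises(ValueError, match="calibrated response"):
            dose_map(exposed, unexp, calibration)


class TestFilmOutputFactor:
    @staticmethod
    def beam_dose_image(peak, half_size_px=40, field_px=22, edge_px=4):
        """Round field with erf-like edges and a flat core, in Gy."""
        from scipy.special import erf

        ax = np.arange(-half_size_px, half_size_px + 1, dtype=float)
        rr = np.hypot(ax[:, None], ax[None, :])
        return peak * 0.5 * (1 - erf((rr - field_px) / edge_px))

    def test_identical_maps_give_unity(self):
        m = self.beam_dose_image(1.0)
        of, unc = film_output_factor([m], [m])
        assert of == pytest.approx(1.0, rel=1e-12)
        assert unc == 0.0

    def test_scaled_field_ratio_recovered_with_film_noise(self):
        """Clinical field at 0.443 of the reference dose, five repeats of
        1% pixel noise: the measured ratio lands on the generator truth."""
        rng = np.random.default_rng(77)
        msr = self.beam_dose_image(2.0)
        clin = 0.443 * msr
        clin_reps = [clin * rng.normal(1, 0.01, clin.shape) for _ in range(5)]
        msr_reps = [msr * rng.normal(1, 0.01, msr.shape) for _ in range(5)]
        of, unc = film_output_factor(clin_reps, msr_reps)
        assert of == pytest.approx(0.443, abs=0.01)
        assert unc > 0
        assert abs(of - 0.443) <= 3 * max(unc, 1e-4)

    def test_ratio_invariant_under_common_rescale(self):
        msr = self.beam_dose_image(1.6)
        clin = 0.5 * msr
        of1, _ = film_output_factor([clin], [msr])
        of2, _ = film_output_factor([2.0 * clin], [2.0 * msr])
        assert of1 == pytest.approx(of2, rel=1e-12)

    def test_uncertainty_tracks_analytic_standard_error(self):
        rng = np.random.default_rng(99)
        msr = self.beam_dose_image(2.0)
        clin = 0.5 * msr
        # repeats differing only by a uniform scale of known sigma
        sigma = 0.01
        clin_reps = [clin * (1 + rng.normal(0, sigma)) for _ in range(5)]
        msr_reps = [msr * (1 + rng.normal(0, sigma)) for _ in range(5)]
        of, unc = film_output_factor(clin_reps, msr_reps)
        analytic = 0.5 * sigma * np.sqrt(2.0 / 5.0)
        assert unc == pytest.approx(analytic, rel=1.0)  # within a factor 2

    def test_empty_repeats_rejected(self):
        with pytest.raises(ValueError):
            film_output_factor([], [self.beam_dose_image(1.0)])


def test_full_film_roundtrip(calibration):
    """Generator film of a beam-shaped dose -> pipeline dose map recovers
    the truth within the pixel-noise budget."""
    truth_img = TestFilmOutputFactor.beam_dose_image(1.5, half_size_px=30,
                                                     field_px=18)
    films, unexp, truth = make_film_set(truth_img, n_repeats=3, seed=55)
    recovered = []
    for film in films:
        dose, spacing = dose_map(film, unexp, calibration)
        recovered.append(dose)
    center = np.mean([d[30, 30] for d in recovered])
    assert center == pytest.approx(1.5, abs=0.03)
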