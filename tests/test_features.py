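import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corefucid.features import (
    CIFeatureVector,
    extract_features,
    match_ci_peaks,
    max_normalize,
    min_ci_filter,
    relative_intensities,
    sum_normalize,
    theoretical_ci_mz,
)
from corefucid.spectra_io import GlycoPSM, Spectrum
from corefucid.synth import sample_feature_cohort, case_spec, synthesize_spectrum

PEPTIDE_MASS = 1500.0


def spectrum_at_all_cis(charge=1, extra=()):
    theo = theoretical_ci_mz(PEPTIDE_MASS, [charge])[:, 0]
    mz = np.concatenate([theo, [m for m, _ in extra]])
    inten = np.concatenate([np.linspace(10, 100, 10), [i for _, i in extra]])
    return Spectrum("s", mz=mz, intensity=inten)


class TestMatching:
    def test_exact_peaks_all_matched(self):
        raw, mask = match_ci_peaks(spectrum_at_all_cis(), PEPTIDE_MASS, charges=[1])
        assert mask.all()
        assert int(mask.sum()) == 10
        assert (raw > 0).all()

    @pytest.mark.parametrize("offset_ppm, expected", [(19.0, True), (25.0, False)])
    def test_tolerance_window_edge(self, offset_ppm, expected):
        y1 = theoretical_ci_mz(PEPTIDE_MASS, [1])[0, 0]
        spec = Spectrum("s", mz=[y1 * (1 + offset_ppm * 1e-6)], intensity=[5.0])
        _, mask = match_ci_peaks(spec, PEPTIDE_MASS, tol_ppm=20, charges=[1])
        assert bool(mask[0]) is expected

    def test_highest_intensity_wins_within_window(self):
        y1 = theoretical_ci_mz(PEPTIDE_MASS, [1])[0, 0]
        spec = Spectrum("s", mz=[y1 * (1 - 10e-6), y1 * (1 + 15e-6)],
                        intensity=[3.0, 9.0])
        raw, _ = match_ci_peaks(spec, PEPTIDE_MASS, charges=[1])
        assert raw[0] == 9.0

    def test_intensity_summed_over_charges(self):
        theo = theoretical_ci_mz(PEPTIDE_MASS, [1, 2])
        spec = Spectrum("s", mz=[theo[0, 0], theo[0, 1]], intensity=[4.0, 6.0])
        raw, mask = match_ci_peaks(spec, PEPTIDE_MASS, charges=[1, 2])
        assert raw[0] == 10.0
        assert mask[0]

    def test_empty_spectrum_all_zero(self):
        spec = Spectrum("s", mz=[], intensity=[])
        raw, mask = match_ci_peaks(spec, PEPTIDE_MASS)
        assert not mask.any()
        assert not raw.any()

    def test_permuting_peaks_changes_nothing(self, rng):
        spec = spectrum_at_all_cis(extra=[(333.3, 50.0), (444.4, 2.0)])
        perm = rng.permutation(spec.n_peaks)
        shuffled = Spectrum("s", mz=spec.mz[perm], intensity=spec.intensity[perm])
        r1, m1 = match_ci_peaks(spec, PEPTIDE_MASS)
        r2, m2 = match_ci_peaks(shuffled, PEPTIDE_MASS)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(m1, m2)


class TestRelativeIntensities:
    def test_base_peak_denominator(self):
        spec = Spectrum("s", mz=[100.0, 200.0], intensity=[100.0, 40.0])
        x = relative_intensities(np.array([50.0] + [0.0] * 9), spec)
        assert x[0] == 0.5

    def test_ci_peak_is_base_peak(self):
        spec = Spectrum("s", mz=[100.0], intensity=[80.0])
        x = relative_intensities(np.array([80.0] + [0.0] * 9), spec)
        assert x[0] == 1.0

    def test_all_zero_spectrum_rejected(self):
        spec = Spectrum("s", mz=[100.0], intensity=[0.0])
        with pytest.raises(ValueError):
            relative_intensities(np.zeros(10), spec)


class TestFilterAndNormalize:
    @pytest.mark.parametrize("n_matched, min_ci, kept", [(3, 3, True), (2, 3, False), (0, 0, True)])
    def test_min_ci_filter(self, n_matched, min_ci, kept):
        x = np.zeros(10)
        x[:n_matched] = 0.5
        vec = CIFeatureVector(scan_id="s", x=x)
        assert min_ci_filter(vec, min_ci) is kept

    def test_max_normalize_example(self):
        x = np.array([1, 2, 4] + [0] * 7, dtype=float)
        np.testing.assert_allclose(max_normalize(x)[:3], [0.25, 0.5, 1.0])
        assert max_normalize(x).max() == 1.0

    def test_sum_normalize_example(self):
        x = np.array([1, 1, 2] + [0] * 7, dtype=float)
        np.testing.assert_allclose(sum_normalize(x)[:3], [0.25, 0.25, 0.5])
        assert sum_normalize(x).sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            max_normalize(np.zeros(10))
        with pytest.raises(ValueError):
            sum_normalize(np.zeros(10))

    @settings(max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_invariance_of_both_normalizations(self, scale, seed):
        x = np.random.default_rng(seed).uniform(0.01, 1.0, 10)
        np.testing.assert_allclose(max_normalize(x * scale), max_normalize(x), rtol=1e-12)
        np.testing.assert_allclose(sum_normalize(x * scale), sum_normalize(x), rtol=1e-12)


class TestEndToEndExtraction:
    def test_synthesized_spectra_recover_intended_intensities(self):
        vectors = sample_feature_cohort(case_spec(), 25, seed=5)
        psms, spectra = [], []
        for i, v in enumerate(vectors):
            psm = GlycoPSM(scan_id=v.scan_id, peptide_mass=1000.0 + 37.0 * i,
                           glycan_composition={"HexNAc": 2, "Hex": 5},
                           source_tag="FUT8_KO")
            psms.append(psm)
            spectra.append(synthesize_spectrum(psm, v.x, noise_peaks=5, seed=i))
        out = extract_features(spectra, psms, norm="sum", min_ci=3)
        by_scan = {v.scan_id: v for v in out}
        checked = 0
        for v in vectors:
            if v.n_matched < 3:
                assert v.scan_id not in by_scan
                continue
            got = by_scan[v.scan_id]
            np.testing.assert_allclose(got.x, v.x, rtol=1e-9, atol=1e-12)
            np.testing.assert_array_equal(got.matched_mask, v.matched_mask)
            checked += 1
        assert checked >= 20

    def test_jitter_inside_tolerance_matches_outside_does_not(self):
        psm = GlycoPSM(scan_id="j", peptide_mass=1800.0,
                       glycan_composition={"HexNAc": 2}, source_tag="OTHER")
        x = np.full(10, 0.3)
        near = synthesize_spectrum(psm, x, jitter_ppm=10, seed=3)
        far = synthesize_spectrum(psm, x, jitter_ppm=30, seed=3)
        _, mask_near = match_ci_peaks(near, 1800.0, tol_ppm=20, charges=[1])
        _, mask_far = match_ci_peaks(far, 1800.0, tol_ppm=20, charges=[1])
        assert mask_near.all()
        assert not mask_far.all()

    def test_explicit_mass_overrides_sequence(self):
        # peptide column present but mass column decides the ion windows
        psm = GlycoPSM(scan_id="s", peptide="GG", peptide_mass=PEPTIDE_MASS,
                       glycan_composition={}, source_tag="OTHER")
        out = extract_features([spectrum_at_all_cis()], [psm], min_ci=3, charges=[1])
        assert len(out) == 1
        assert out[0].n_matched == 10
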