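import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzldt.io_model import Spectrum
from mzldt.preprocess import (
    FeatureMatrix,
    MissingStandardError,
    align,
    filter_features,
    link_isotopologues,
    preprocess_spectra,
    recalibrate_intensities,
    restrict_mz_range,
)


def spectrum(sample_id, pairs):
    return Spectrum.from_peaks(sample_id, [p[0] for p in pairs], [p[1] for p in pairs])


class TestRecalibration:
    def test_division_by_standard_peak(self):
        s = spectrum("a", [(180.0, 500.0), (423.169, 2000.0)])
        out = recalibrate_intensities(s)
        assert dict(out.peaks) == {423.169: 1.0, 180.0: 0.25}

    def test_identity_when_standard_is_one(self):
        s = spectrum("a", [(180.0, 0.25), (423.169, 1.0)])
        out = recalibrate_intensities(s)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_missing_standard_names_sample(self):
        s = spectrum("subject7", [(180.0, 500.0)])
        with pytest.raises(MissingStandardError, match="subject7"):
            recalibrate_intensities(s)

    def test_nearest_peak_within_tolerance_used(self):
        s = spectrum("a", [(423.167, 10.0), (423.172, 40.0)])
        out = recalibrate_intensities(s, tol=0.005)
        # 423.167 is nearer (0.002 Da) than 423.172 (0.003 Da) → its intensity becomes 1
        assert out.intensity[0] == 1.0


class TestAlign:
    def test_single_spectrum_is_identity(self):
        s = spectrum("a", [(100.0, 1.0), (200.0, 2.0)])
        fm = align([s], tol=0.005)
        np.testing.assert_allclose(fm.mz, [100.0, 200.0])
        np.testing.assert_allclose(fm.intensities[:, 0], [1.0, 2.0])

    def test_gap_below_tolerance_merges(self):
        fm = align([spectrum("a", [(100.0000, 1.0)]), spectrum("b", [(100.0040, 3.0)])], tol=0.005)
        assert fm.n_features == 1
        assert np.all(fm.intensities > 0)
        # consensus is the intensity-weighted mean
        np.testing.assert_allclose(fm.mz[0], (100.0 * 1 + 100.004 * 3) / 4)

    def test_gap_above_tolerance_splits(self):
        fm = align([spectrum("a", [(100.0000, 1.0)]), spectrum("b", [(100.0060, 3.0)])], tol=0.005)
        assert fm.n_features == 2
        assert (fm.intensities == 0).sum() == 2  # one zero cell per feature

    def test_within_sample_peaks_summed(self):
        fm = align([spectrum("a", [(100.000, 1.0), (100.004, 2.0)])], tol=0.005)
        assert fm.n_features == 1
        assert fm.intensities[0, 0] == 3.0

    def test_tolerance_must_be_positive(self):
        with pytest.raises(ValueError):
            align([spectrum("a", [(100.0, 1.0)])], tol=0.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(
                    st.floats(min_value=50, max_value=500, allow_nan=False),
                    st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
                ),
                min_size=1,
                max_size=25,
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_alignment_invariants(self, peak_sets):
        spectra = [
            Spectrum.from_peaks(f"s{k}", [p[0] for p in ps], [p[1] for p in ps])
            for k, ps in enumerate(peak_sets)
        ]
        tol = 0.005
        fm = align(spectra, tol)
        # conservation: total intensity of input peaks is preserved
        np.testing.assert_allclose(
            fm.intensities.sum(), sum(s.intensity.sum() for s in spectra), rtol=1e-9
        )
        # feature boundaries equal an independent gap-cut oracle on pooled m/z
        pooled = np.sort(np.concatenate([s.mz for s in spectra]))
        oracle_features = 1 + int((np.diff(pooled) > tol).sum())
        assert fm.n_features == oracle_features
        # permutation invariance of spectrum order (columns realigned by id)
        fm2 = align(spectra[::-1], tol)
        np.testing.assert_allclose(fm2.mz, fm.mz, atol=1e-9)
        cols = [fm2.sample_ids.index(s) for s in fm.sample_ids]
        np.testing.assert_allclose(fm2.intensities[:, cols], fm.intensities, rtol=1e-9)

    def test_feature_matrix_tsv_round_trip(self, tmp_path):
        fm = align([spectrum("a", [(100.0, 1.0), (200.0, 2.0)]), spectrum("b", [(100.002, 4.0)])])
        path = tmp_path / "fm.tsv"
        fm.to_tsv(str(path))
        fm2 = FeatureMatrix.from_tsv(str(path))
        np.testing.assert_allclose(fm2.mz, fm.mz, atol=1e-5)
        np.testing.assert_allclose(fm2.intensities, fm.intensities, rtol=1e-5)
        assert fm2.sample_ids == fm.sample_ids


class TestFilter:
    def _matrix(self, nonzero_counts, n_samples=56):
        mz = np.arange(len(nonzero_counts), dtype=float) + 100.0
        mat = np.zeros((len(nonzero_counts), n_samples))
        for i, k in enumerate(nonzero_counts):
            mat[i, :k] = 1.0
        return FeatureMatrix(mz, mat, [f"s{j}" for j in range(n_samples)])

    def test_nine_of_56_dropped_ten_kept(self):
        fm = filter_features(self._matrix([9, 10, 56]))
        np.testing.assert_allclose(fm.mz, [101.0, 102.0])

    def test_min_nonzero_one_keeps_everything_present(self):
        fm0 = self._matrix([1, 5, 56])
        fm = filter_features(fm0, min_nonzero=1)
        assert fm.n_features == fm0.n_features

    def test_min_nonzero_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_features(self._matrix([1]), min_nonzero=0)


class TestIsotopologues:
    def _pair_matrix(self, mz2, corr_sign=1.0, n=20):
        rng = np.random.default_rng(0)
        base = np.exp(rng.normal(5, 1, n))
        other = 0.1 * base if corr_sign > 0 else np.exp(rng.normal(5, 1, n))
        mat = np.vstack([base, other])
        return FeatureMatrix(np.array([181.0707, mz2]), mat, [f"s{j}" for j in range(n)])

    def test_correlated_pair_at_isotope_spacing_linked(self):
        fm = link_isotopologues(self._pair_matrix(182.0741))
        assert fm.isotope_parent.tolist() == [-1, 0]

    def test_uncorrelated_pair_not_linked(self):
        fm = link_isotopologues(self._pair_matrix(182.0741, corr_sign=-1.0))
        assert fm.isotope_parent.tolist() == [-1, -1]

    def test_no_pair_within_spacing_tolerance(self):
        fm = link_isotopologues(self._pair_matrix(182.5))
        assert fm.isotope_parent.tolist() == [-1, -1]


def test_mz_range_restriction_is_inclusive():
    s = spectrum("a", [(44.9, 1.0), (45.0, 2.0), (423.169, 3.0), (1000.0, 4.0), (1000.1, 5.0)])
    out = restrict_mz_range(s, 45.0, 1000.0)
    assert out.mz.tolist() == [45.0, 423.169, 1000.0]


def test_recalibration_removes_per_sample_scale(sim_default):
    """The internal-standard feature column must be exactly 1 after the
    recalibrate → align chain, cancelling the simulated global scales."""
    fm = preprocess_spectra(sim_default.spectra)
    i = int(np.argmin(np.abs(fm.mz - 423.169)))
    assert abs(fm.mz[i] - 423.169) < 1e-6
    np.testing.assert_allclose(fm.intensities[i], 1.0, rtol=1e-12)
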