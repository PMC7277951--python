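"""Spectrum preprocessing: internal-standard recalibration, cross-sample m/z
alignment into a feature matrix, prevalence filtering and isotopologue
linking.

Recalibration divides every intensity in a spectrum by the intensity of the
internal-standard peak (losartan, m/z 423.169 in positive mode), so the
standard's recalibrated intensity is exactly 1 and any per-sample global
intensity scale cancels.

Alignment pools all peaks from all samples, sorts them by m/z and cuts the
sorted sequence wherever the gap between adjacent peaks exceeds the
tolerance (greedy single-linkage with a gap cut).  Each resulting cluster is
one feature; its consensus m/z is the intensity-weighted mean of the member
peaks.  A sample contributing several peaks to one feature has their
intensities summed; samples contributing none get 0 ("not detected").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_model import Spectrum

logger = logging.getLogger(__name__)

DEFAULT_STANDARD_MZ = 423.169   # losartan [M+H]+, positive mode
DEFAULT_TOL = 0.005             # Da, matches the metabolite search tolerance
ISOTOPE_DELTA = 1.00336         # Da, 13C − 12C mass difference
DEFAULT_MZ_RANGE = (45.0, 1000.0)  # detection bound; acquisition ranges vary by setup


def restrict_mz_range(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Drop peaks outside the detection m/z bound [lo, hi]."""
    keep = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    return Spectrum(spectrum.sample_id, spectrum.mz[keep], spectrum.intensity[keep])


class MissingStandardError(ValueError):
    """No peak near the internal-standard m/z in a spectrum."""


@dataclass
class FeatureMatrix:
    """Aligned features × samples intensity table.

    ``mz`` is the strictly increasing consensus m/z per feature,
    ``intensities`` the (features × samples) matrix with 0 meaning "not
    detected", and ``isotope_parent`` maps isotopologue features to the row
    index of their monoisotopic parent (−1 = not an isotopologue).
    """

    mz: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    isotope_parent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.isotope_parent is None:
            self.isotope_parent = np.full(self.mz.size, -1, dtype=int)
        self.isotope_parent = np.asarray(self.isotope_parent, dtype=int)
        if self.intensities.shape != (self.mz.size, len(self.sample_ids)):
            raise ValueError("intensity matrix shape does not match features × samples")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("consensus m/z must be strictly increasing")

    @property
    def n_features(self) -> int:
        return int(self.mz.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def monoisotopic_mask(self) -> np.ndarray:
        return self.isotope_parent < 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.sample_ids)
        df.insert(0, "mz", self.mz)
        df.insert(1, "isotope_parent", self.isotope_parent)
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns)
        has_iso = "isotope_parent" in cols
        sample_cols = [c for c in cols if c not in ("mz", "isotope_parent")]
        return cls(
            mz=df["mz"].to_numpy(float),
            intensities=df[sample_cols].to_numpy(float),
            sample_ids=sample_cols,
            isotope_parent=df["isotope_parent"].to_numpy(int) if has_iso else None,
        )


def recalibrate_intensities(
    spectrum: Spectrum,
    standard_mz: float = DEFAULT_STANDARD_MZ,
    tol: float = DEFAULT_TOL,
) -> Spectrum:
    """Divide every intensity by that of the peak nearest ``standard_mz``.

    Raises :class:`MissingStandardError` (naming the sample) when no peak
    lies within ``tol`` of the standard.
    """
    if len(spectrum) == 0:
        raise MissingStandardError(f"{spectrum.sample_id}: empty spectrum")
    dist = np.abs(spectrum.mz - standard_mz)
    i = int(np.argmin(dist))
    if dist[i] > tol:
        raise MissingStandardError(
            f"{spectrum.sample_id}: no peak within {tol} Da of internal standard m/z {standard_mz}"
        )
    ref = spectrum.intensity[i]
    if ref <= 0:
        raise MissingStandardError(f"{spectrum.sample_id}: internal-standard peak has zero intensity")
    return Spectrum(spectrum.sample_id, spectrum.mz, spectrum.intensity / ref)


def total_intensity_normalize(spectrum: Spectrum) -> Spectrum:
    """Alternative normalizer: divide by the summed intensity of the spectrum."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError(f"{spectrum.sample_id}: zero total intensity")
    return Spectrum(spectrum.sample_id, spectrum.mz, spectrum.intensity / total)


def align(spectra: Sequence[Spectrum], tol: float = DEFAULT_TOL) -> FeatureMatrix:
    """Greedy gap-cut single-linkage alignment of pooled peaks.

    Deterministic and independent of the order of ``spectra`` (up to
    floating-point addition order): features depend only on the pooled m/z
    multiset.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among spectra")

    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    samp = np.concatenate([np.full(len(s), k, dtype=int) for k, s in enumerate(spectra)])
    # sort by (mz, sample) so tie order does not depend on input order
    order = np.lexsort((samp, mz))
    mz, inten, samp = mz[order], inten[order], samp[order]

    cut = np.diff(mz) > tol
    feature_of = np.concatenate(([0], np.cumsum(cut)))
    n_feat = int(feature_of[-1]) + 1

    weight_sum = np.zeros(n_feat)
    wmz_sum = np.zeros(n_feat)
    count = np.zeros(n_feat)
    mz_sum = np.zeros(n_feat)
    np.add.at(weight_sum, feature_of, inten)
    np.add.at(wmz_sum, feature_of, inten * mz)
    np.add.at(count, feature_of, 1.0)
    np.add.at(mz_sum, feature_of, mz)
    with np.errstate(invalid="ignore"):
        consensus = np.where(weight_sum > 0, wmz_sum / np.maximum(weight_sum, 1e-300), mz_sum / count)

    matrix = np.zeros((n_feat, len(spectra)))
    np.add.at(matrix, (feature_of, samp), inten)

    # guard against zero-intensity-weight collapse breaking monotonicity
    if np.any(np.diff(consensus) <= 0):
        consensus = mz_sum / count
    return FeatureMatrix(consensus, matrix, ids)


def filter_features(fm: FeatureMatrix, min_nonzero: int = 10) -> FeatureMatrix:
    """Keep features detected (intensity > 0) in at least ``min_nonzero`` samples.

    The default of 10 keeps features present in more than nine samples.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    keep = (fm.intensities > 0).sum(axis=1) >= min_nonzero
    idx_map = {old: new for new, old in enumerate(np.flatnonzero(keep))}
    parent = np.array(
        [idx_map.get(p, -1) if p >= 0 else -1 for p in fm.isotope_parent[keep]], dtype=int
    )
    return FeatureMatrix(fm.mz[keep], fm.intensities[keep], list(fm.sample_ids), parent)


def _pairwise_nonzero_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson correlation on pairwise-complete nonzero cells."""
    mask = (x > 0) & (y > 0)
    n = int(mask.sum())
    if n < 3:
        return np.nan, n
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan, n
    return float(np.corrcoef(xv, yv)[0, 1]), n


def link_isotopologues(
    fm: FeatureMatrix,
    delta: float = ISOTOPE_DELTA,
    tol: float = DEFAULT_TOL,
    min_corr: float = 0.7,
) -> FeatureMatrix:
    """Mark features as isotopologues of a lighter monoisotopic feature.

    Feature j is linked to feature i when mz_j ≈ mz_i + k·delta (k = 1, 2)
    within ``tol`` and the across-sample intensity correlation (computed
    pairwise on samples where both are detected) is at least ``min_corr``.
    Isotopologues stay in the matrix but are excluded from candidate search.
    """
    if fm.n_samples < 2:
        raise ValueError("need at least 2 samples to correlate intensities")
    parent = fm.isotope_parent.copy()
    mz = fm.mz
    for i in range(fm.n_features):
        if parent[i] >= 0:
            continue  # isotopologues cannot themselves be parents
        for k in (1, 2):
            target = mz[i] + k * delta
            lo = np.searchsorted(mz, target - tol, side="left")
            hi = np.searchsorted(mz, target + tol, side="right")
            for j in range(lo, hi):
                if j == i or parent[j] >= 0:
                    continue
                r, n = _pairwise_nonzero_corr(fm.intensities[i], fm.intensities[j])
                if n >= 2 and not np.isnan(r) and r >= min_corr:
                    parent[j] = i
    return FeatureMatrix(fm.mz, fm.intensities, list(fm.sample_ids), parent)


def preprocess_spectra(
    spectra: Sequence[Spectrum],
    standard_mz: float = DEFAULT_STANDARD_MZ,
    tol: float = DEFAULT_TOL,
    min_nonzero: int = 10,
    min_corr: float = 0.7,
    normalizer: Callable[[Spectrum], Spectrum] | None = None,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
) -> FeatureMatrix:
    """Full preprocessing chain: restrict m/z range, normalize, align,
    filter, link isotopologues.

    ``normalizer`` defaults to internal-standard division at ``standard_mz``.
    """
    spectra = [restrict_mz_range(s, *mz_range) for s in spectra]
    if normalizer is None:
        normed = [recalibrate_intensities(s, standard_mz, tol) for s in spectra]
    else:
        normed = [normalizer(s) for s in spectra]
    fm = align(normed, tol)
    fm = filter_features(fm, min_nonzero)
    return link_isotopologues(fm, tol=tol, min_corr=min_corr)
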