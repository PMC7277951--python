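"""Accurate-mass candidate search.

Maps each non-isotopologue feature m/z to candidate metabolites assuming
singly charged positive-mode adducts [M+H]+, [M+Na]+ and [M+K]+, within an
inclusive mass tolerance (default 0.005 Da).  The metabolite table is kept
sorted by neutral mass, so each (feature, adduct) query is a binary-search
window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import MetaboliteDB
from .preprocess import FeatureMatrix

# singly charged cation adduct offsets in Da (cation mass minus one electron)
ADDUCT_OFFSETS: dict[str, float] = {
    "M+H": 1.007276,
    "M+Na": 22.989218,
    "M+K": 38.963158,
}

DEFAULT_TOL = 0.005

CANDIDATE_COLUMNS = ["feature_index", "metabolite_id", "adduct", "mass_error"]


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of the singly charged ``adduct`` ion of a neutral metabolite."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    try:
        return neutral_mass + ADDUCT_OFFSETS[adduct]
    except KeyError:
        raise ValueError(f"unknown adduct {adduct!r}; expected one of {sorted(ADDUCT_OFFSETS)}") from None


def match_candidates(
    fm: FeatureMatrix, db: MetaboliteDB, tol: float = DEFAULT_TOL
) -> pd.DataFrame:
    """All (feature, metabolite, adduct) matches within ``tol`` Da (inclusive).

    Isotopologue features (``isotope_parent >= 0``) are skipped; features
    with no match are absent from the result.  Columns:
    feature_index, metabolite_id, adduct, mass_error (observed − theoretical).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    rows: list[tuple[int, str, str, float]] = []
    mono = fm.monoisotopic_mask()
    for i in np.flatnonzero(mono):
        fmz = fm.mz[i]
        for adduct, offset in ADDUCT_OFFSETS.items():
            neutral = fmz - offset
            for j in db.mass_window(neutral - tol, neutral + tol):
                err = fmz - (db.masses[j] + offset)
                if abs(err) <= tol:
                    rows.append((int(i), db.ids[j], adduct, float(err)))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
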