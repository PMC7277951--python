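"""Shared helpers for the test suite and acceptance checks."""

from __future__ import annotations

import numpy as np

from mzldt import annotate, dbsearch, preprocess, synthgen
from mzldt.preprocess import FeatureMatrix
from mzldt.synthgen import SimResult


def feature_truth_map(sim: SimResult, fm: FeatureMatrix, tol: float = 0.005) -> dict[int, str]:
    """feature index -> planted metabolite id, matched by consensus m/z."""
    out: dict[int, str] = {}
    for _, row in sim.signal_truth().iterrows():
        d = np.abs(fm.mz - row["mz"])
        i = int(np.argmin(d))
        if d[i] <= tol:
            out[i] = row["metabolite_id"]
    return out


def annotation_recovery(sim: SimResult, params=None):
    """Run preprocess → search → annotate on a simulated dataset.

    Returns (recovery, baseline): the fraction of planted features whose
    accepted annotation set contains the true metabolite, and the expected
    accuracy of a uniform random pick among each feature's candidates
    (enumerated on the fixture).
    """
    fm = preprocess.preprocess_spectra(sim.spectra)
    cands = dbsearch.match_candidates(fm, sim.metabolite_db)
    at = annotate.annotate_features(fm, cands, sim.pathway_db, params)
    truth = feature_truth_map(sim, fm)
    accepted = at[at["accepted"]].groupby("feature_index")["metabolite_id"].apply(set)
    n_cands = cands.groupby("feature_index").size()
    n = recovered = 0
    baseline = 0.0
    for i, true_id in truth.items():
        if i not in n_cands.index:
            continue
        n += 1
        baseline += 1.0 / n_cands.loc[i]
        if true_id in accepted.get(i, set()):
            recovered += 1
    return recovered / n, baseline / n


def brute_force_candidates(fm, db, tol: float):
    """O(features × records × adducts) exhaustive reference for match_candidates."""
    rows = set()
    for i in range(fm.n_features):
        if fm.isotope_parent[i] >= 0:
            continue
        for adduct, offset in dbsearch.ADDUCT_OFFSETS.items():
            for j in range(len(db)):
                if abs(fm.mz[i] - (db.masses[j] + offset)) <= tol:
                    rows.add((i, db.ids[j], adduct))
    return rows
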