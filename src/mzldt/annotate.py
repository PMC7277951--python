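"""Biochemical-context-driven putative annotation.

Concentrations of metabolites in the same pathway tend to correlate across
subjects.  For a feature with several accurate-mass candidates, the true
candidate is the one whose pathway neighborhood is supported by the data:
features whose intensities correlate with the feature of interest should
carry candidates lying in the same pathways.  Each candidate is given a
context score — the number of correlated neighbor features holding at least
one candidate sharing a pathway with it (each neighbor counted at most
once) — and the maximal-scoring candidate(s) above a minimum score are
accepted as the putative annotation (identification level 2: accurate mass
plus biochemical context).  Ties at the maximum are all accepted and
flagged ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import PathwayDB
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["feature_index", "metabolite_id", "context_score", "accepted", "ambiguous"]


@dataclass(frozen=True)
class AnnotationParams:
    """Knobs of the context-driven annotation.

    corr_threshold
        Minimum across-sample correlation for a feature to count as a
        neighbor (default 0.7 — conservative, near-proportional profiles).
    min_context_score
        Minimum number of supporting neighbors for acceptance (default 2,
        so a single coincidental neighbor never annotates).
    corr_method
        "pearson" (default) or "spearman" (mid-ranks of nonzero cells).
    log_transform
        Correlate log-intensities (default True; intensities are
        multiplicative).
    min_overlap
        Minimum pairwise-complete nonzero samples for a pair to be
        evaluated (default 10).
    """

    corr_threshold: float = 0.7
    min_context_score: int = 2
    corr_method: str = "pearson"
    log_transform: bool = True
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.min_context_score < 1:
            raise ValueError("min_context_score must be >= 1")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError("corr_method must be 'pearson' or 'spearman'")


def _transformed(fm: FeatureMatrix, params: AnnotationParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature transformed values and nonzero mask."""
    x = fm.intensities
    mask = x > 0
    vals = np.zeros_like(x)
    if params.corr_method == "spearman":
        for i in range(x.shape[0]):
            nz = mask[i]
            if nz.any():
                vals[i, nz] = pd.Series(x[i, nz]).rank().to_numpy()
    elif params.log_transform:
        vals[mask] = np.log(x[mask])
    else:
        vals[mask] = x[mask]
    return vals, mask


def pairwise_correlations(fm: FeatureMatrix, params: AnnotationParams | None = None) -> np.ndarray:
    """All-pairs correlation on pairwise-complete nonzero cells.

    Returns an (F × F) matrix with NaN on the diagonal, for pairs with fewer
    than ``min_overlap`` complete observations, and for constant pairs.
    Spearman uses per-feature mid-ranks of the nonzero cells (ranked once,
    not re-ranked per pair).
    """
    params = params or AnnotationParams()
    vals, mask = _transformed(fm, params)
    m = mask.astype(float)
    xv = vals * m
    n = m @ m.T
    sx = xv @ m.T            # sum of x over common cells, rows = x-feature
    sxx = (xv * xv) @ m.T
    sxy = xv @ xv.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        vary = varx.T
        denom = np.sqrt(varx * vary)
        r = cov / denom
    r[n < params.min_overlap] = np.nan
    r[~np.isfinite(r)] = np.nan
    np.fill_diagonal(r, np.nan)
    return r


def correlation_neighbors(
    fm: FeatureMatrix,
    i: int,
    params: AnnotationParams | None = None,
    corr_matrix: np.ndarray | None = None,
) -> set[int]:
    """Features whose intensity profile correlates with feature ``i`` at or
    above the threshold (pairwise-complete nonzero cells)."""
    params = params or AnnotationParams()
    if corr_matrix is None:
        corr_matrix = pairwise_correlations(fm, params)
    row = corr_matrix[i]
    return set(int(j) for j in np.flatnonzero(np.nan_to_num(row, nan=-2.0) >= params.corr_threshold))


def context_score(
    metabolite_id: str,
    feature_index: int,
    neighbors: set[int],
    candidates: pd.DataFrame,
    pdb: PathwayDB,
) -> int:
    """Number of neighbor features supporting candidate ``metabolite_id``.

    A neighbor feature supports the candidate when at least one of its own
    candidates shares a pathway with it; each neighbor counts at most once.
    """
    own = candidates[candidates["feature_index"] == feature_index]
    if metabolite_id not in set(own["metabolite_id"]):
        raise ValueError(f"{metabolite_id!r} is not a candidate of feature {feature_index}")
    inv = pdb.pathways_of()
    my_pw = inv.get(metabolite_id, set())
    if not my_pw:
        return 0
    score = 0
    grouped = candidates.groupby("feature_index")["metabolite_id"]
    for j in neighbors:
        if j == feature_index:
            continue
        try:
            cands_j = grouped.get_group(j)
        except KeyError:
            continue
        if any(my_pw & inv.get(c, set()) for c in cands_j):
            score += 1
    return score


def annotate_features(
    fm: FeatureMatrix,
    candidates: pd.DataFrame,
    pdb: PathwayDB,
    params: AnnotationParams | None = None,
) -> pd.DataFrame:
    """Score every candidate of every feature and accept the best-supported.

    For each feature the maximal-scoring candidate(s) with context score at
    least ``min_context_score`` are accepted; ties are all accepted and
    flagged ambiguous.  Deterministic: identical inputs give identical
    tables.  Columns: feature_index, metabolite_id, context_score,
    accepted, ambiguous.
    """
    params = params or AnnotationParams()
    if len(candidates) == 0:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    bad = set(candidates["feature_index"]) - set(range(fm.n_features))
    if bad:
        raise ValueError(f"candidate feature indices not in matrix: {sorted(bad)}")

    corr = pairwise_correlations(fm, params)
    inv = pdb.pathways_of()
    # pathway-index union of each feature's candidates, for fast neighbor support
    feat_pw: dict[int, set[int]] = {}
    for j, grp in candidates.groupby("feature_index"):
        u: set[int] = set()
        for c in grp["metabolite_id"]:
            u |= inv.get(c, set())
        feat_pw[int(j)] = u

    rows = []
    thr = params.corr_threshold
    for i, grp in candidates.groupby("feature_index"):
        i = int(i)
        nbr_row = np.nan_to_num(corr[i], nan=-2.0)
        neighbors = [int(j) for j in np.flatnonzero(nbr_row >= thr) if int(j) in feat_pw and j != i]
        scores = []
        for c in grp["metabolite_id"]:
            my_pw = inv.get(c, set())
            s = sum(1 for j in neighbors if my_pw & feat_pw[j]) if my_pw else 0
            scores.append(s)
        best = max(scores)
        accepted = [s == best and s >= params.min_context_score for s in scores]
        ambiguous = sum(accepted) > 1
        for c, s, a in zip(grp["metabolite_id"], scores, accepted):
            rows.append((i, c, s, a, a and ambiguous))
    out = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return out.sort_values(["feature_index", "metabolite_id"], ignore_index=True)


def annotated_universe(annotations: pd.DataFrame) -> set[str]:
    """Deduplicated accepted metabolite ids — the experiment's annotated universe."""
    if len(annotations) == 0:
        return set()
    return set(annotations.loc[annotations["accepted"], "metabolite_id"])


def accepted_by_feature(annotations: pd.DataFrame) -> dict[int, set[str]]:
    """feature index → set of accepted metabolite ids."""
    if len(annotations) == 0:
        return {}
    acc = annotations[annotations["accepted"].astype(bool)]
    return {int(i): set(g["metabolite_id"]) for i, g in acc.groupby("feature_index")}
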