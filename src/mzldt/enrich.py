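"""Permutation-based pathway overrepresentation.

A selected metabolite set is projected onto the pathway table (observed
member count k_p per pathway) and compared with a null built from repeated
random draws of the same number of metabolites (default 30,000 draws,
without replacement) from the annotated universe.  The representation score
of a pathway is the observed-to-expected fold k_p / max(null mean, 1/R);
the empirical p-value is the add-one tail (1 + #{draws ≥ k_p}) / (R + 1),
so it is never exactly zero.  Group comparisons report the ratio of mean
case to mean control scores ("fold overrepresentation") and a two-sided
Wilcoxon rank-sum p-value per pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PathwayDB

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 30_000


def project_counts(selected: set[str] | list[str], pdb: PathwayDB) -> np.ndarray:
    """Observed member count k_p = |selected ∩ members_p| for every pathway.

    Metabolite ids absent from every pathway are allowed (they simply do
    not project); ids are deduplicated first.
    """
    sel = set(selected)
    known = set().union(*pdb.members) if len(pdb) else set()
    unknown = sel - known
    if unknown:
        logger.info("%d selected ids not in any pathway (ignored)", len(unknown))
    return np.array([len(sel & mem) for mem in pdb.members], dtype=float)


@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of per-pathway counts for draws of ``n_sel`` ids."""

    n_sel: int
    n_draws: int
    universe: tuple[str, ...]
    mean: np.ndarray          # per pathway
    sd: np.ndarray            # per pathway (population sd over draws)
    hist: np.ndarray          # (n_pathways × (max count + 1)) draw-count histogram

    def tail_prob(self, k: np.ndarray) -> np.ndarray:
        """Add-one empirical P(count ≥ k_p) per pathway."""
        k = np.asarray(k)
        out = np.empty(len(self.mean))
        for p in range(len(self.mean)):
            kp = int(np.ceil(k[p]))
            ge = self.hist[p, min(kp, self.hist.shape[1]) :].sum() if kp <= self.hist.shape[1] else 0
            if kp <= 0:
                ge = self.n_draws
            out[p] = (1.0 + ge) / (self.n_draws + 1.0)
        return out


def permutation_null(
    n_sel: int,
    universe: set[str] | list[str],
    pdb: PathwayDB,
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> PermutationNull:
    """Null per-pathway count statistics from ``n_draws`` random selections.

    Each draw takes ``n_sel`` metabolite ids uniformly without replacement
    from ``universe``.  Reproducible given the seed/generator.
    """
    universe = tuple(sorted(set(universe)))
    n_univ = len(universe)
    if not 1 <= n_sel <= n_univ:
        raise ValueError(f"n_sel must be in [1, {n_univ}], got {n_sel}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    member = pdb.membership_matrix(universe)            # (N × P) bool
    # vectorized draws: smallest n_sel of a random row are the selection
    keys = rng.random((n_draws, n_univ))
    idx = np.argpartition(keys, n_sel - 1, axis=1)[:, :n_sel]
    sel = np.zeros((n_draws, n_univ), dtype=np.float32)
    np.put_along_axis(sel, idx, 1.0, axis=1)
    counts = sel @ member.astype(np.float32)            # (R × P)
    counts = np.rint(counts).astype(np.int64)

    mean = counts.mean(axis=0)
    sd = counts.std(axis=0)
    kmax = int(counts.max(initial=0))
    hist = np.zeros((len(pdb), kmax + 1), dtype=np.int64)
    for p in range(len(pdb)):
        hist[p] = np.bincount(counts[:, p], minlength=kmax + 1)
    return PermutationNull(n_sel, n_draws, universe, mean, sd, hist)


def representation_scores(
    k: np.ndarray, null: PermutationNull, pdb: PathwayDB, subject_id: str = ""
) -> pd.DataFrame:
    """Per-pathway representation scores and empirical p-values.

    score = k_p / max(null mean, 1/R): observed-to-expected fold, with a
    1/R floor so pathways never hit in the null still get a finite score.
    A Benjamini–Hochberg column is included alongside the raw empirical p.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != null.mean.shape:
        raise ValueError("count vector and null statistics index different pathways")
    floor = 1.0 / null.n_draws
    score = k / np.maximum(null.mean, floor)
    p_emp = null.tail_prob(k)
    return pd.DataFrame(
        {
            "pathway_id": pdb.pathway_ids,
            "pathway_name": pdb.names,
            "k": k.astype(int),
            "null_mean": null.mean,
            "null_sd": null.sd,
            "score": score,
            "p_empirical": p_emp,
            "p_bh": stats.false_discovery_control(p_emp),
        }
    ).assign(subject=subject_id)


class NullCache:
    """Cache of permutation nulls keyed by selection size.

    Scoring a cohort asks for one null per distinct selection size; draws
    are reused across subjects with the same size.  Child seeds are spawned
    deterministically from the base seed.
    """

    def __init__(self, universe, pdb: PathwayDB, n_draws: int = DEFAULT_DRAWS, seed: int = 0):
        self.universe = tuple(sorted(set(universe)))
        self.pdb = pdb
        self.n_draws = n_draws
        self._seed = seed
        self._cache: dict[int, PermutationNull] = {}

    def get(self, n_sel: int) -> PermutationNull:
        if n_sel not in self._cache:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=self._seed, spawn_key=(n_sel,)))
            self._cache[n_sel] = permutation_null(
                n_sel, self.universe, self.pdb, self.n_draws, rng
            )
        return self._cache[n_sel]


def score_profile(
    selected: set[str],
    universe: set[str] | list[str],
    pdb: PathwayDB,
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    null: PermutationNull | None = None,
) -> pd.DataFrame:
    """Project a selection and score it against its permutation null.

    An empty selection yields all-zero scores (nothing to project).
    """
    k = project_counts(selected, pdb)
    n_sel = len(set(selected))
    if n_sel == 0:
        return pd.DataFrame(
            {
                "pathway_id": pdb.pathway_ids,
                "pathway_name": pdb.names,
                "k": 0,
                "null_mean": 0.0,
                "null_sd": 0.0,
                "score": 0.0,
                "p_empirical": 1.0,
                "p_bh": 1.0,
            }
        ).assign(subject=subject_id)
    if null is None:
        null = permutation_null(n_sel, universe, pdb, n_draws, seed)
    return representation_scores(k, null, pdb, subject_id)


def fold_change(mean_case: float, mean_control: float) -> float:
    """Case-to-control ratio of mean representation scores, rounded to one
    decimal for reporting (use the raw ratio for further arithmetic)."""
    if mean_control <= 0:
        raise ZeroDivisionError("control mean score must be positive for a fold")
    return round(mean_case / mean_control, 1)


def ranksum_test(case_scores, control_scores) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the combined sample size is ≤ 12 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Identical constant groups give p = 1.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def compare_groups(
    profiles: dict[str, pd.DataFrame], groups: dict[str, str], pdb: PathwayDB
) -> pd.DataFrame:
    """Case-vs-control pathway table: mean scores, fold, rank-sum p.

    ``profiles`` maps sample id → its per-pathway score table (one row per
    pathway, in ``pdb`` order); ``groups`` maps sample id → "case"/"control".
    Fold is reported both raw and rounded to one decimal; a control mean of
    zero yields NaN fold (not available).
    """
    case_ids = [s for s in profiles if groups[s] == "case"]
    ctrl_ids = [s for s in profiles if groups[s] == "control"]
    if not case_ids or not ctrl_ids:
        raise ValueError("need at least one case and one control profile")
    case_mat = np.column_stack([profiles[s]["score"].to_numpy() for s in case_ids])
    ctrl_mat = np.column_stack([profiles[s]["score"].to_numpy() for s in ctrl_ids])
    mean_case = case_mat.mean(axis=1)
    mean_ctrl = ctrl_mat.mean(axis=1)
    folds = np.full(len(pdb), np.nan)
    folds_r = np.full(len(pdb), np.nan)
    pvals = np.ones(len(pdb))
    for p in range(len(pdb)):
        if mean_ctrl[p] > 0:
            folds[p] = mean_case[p] / mean_ctrl[p]
            folds_r[p] = round(folds[p], 1)
        pvals[p] = ranksum_test(case_mat[p], ctrl_mat[p])
    return pd.DataFrame(
        {
            "pathway_id": pdb.pathway_ids,
            "pathway_name": pdb.names,
            "mean_case_score": mean_case,
            "mean_control_score": mean_ctrl,
            "fold": folds,
            "fold_rounded": folds_r,
            "ranksum_p": pvals,
        }
    )
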