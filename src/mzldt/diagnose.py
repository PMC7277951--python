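"""Per-subject diagnostic scoring.

A subject's deviating metabolites are found by Z-scoring each feature's
intensity against the control cohort: z = (x − mean_controls)/sd_controls,
with the subject itself left out of the control statistics when it is a
control (leave-one-out).  Features with |z| > 1.64 (one-sided 5% of a
normal) map through their accepted annotations to a selected metabolite
set, which is scored by permutation pathway overrepresentation.  The
diagnostic score D is the sum of representation scores over a fixed panel
of the 20 top disease-associated pathways; D above a threshold (defaults
12 for screening, 340 for high confidence) labels the subject as carrying
the disease pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import accepted_by_feature
from .enrich import DEFAULT_DRAWS, NullCache, score_profile
from .io_model import PathwayDB
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_Z_CRIT = 1.64
DEFAULT_THRESHOLDS = (12.0, 340.0)
PANEL_SIZE = 20

# The published 20-pathway early-PD panel (editable; map to your pathway-DB
# ids with `panel_ids_from_names`).
PD_PANEL_NAMES: tuple[str, ...] = (
    "Transcription/translation",
    "Dopa-responsive dystonia",
    "Fatty acid elongation in mitochondria",
    "Long-chain-3-hydroxyacyl-coa dehydrogenase deficiency (LCHAD)",
    "Hyperphenylalaninemia due to guanosine triphosphate cyclohydrolase deficiency",
    "Hyperphenylalaninemia due to 6-pyruvoyltetrahydropterin synthase (PTPS) deficiency",
    "Hyperphenylalaninemia due to DHPR deficiency",
    "Pterine biosynthesis",
    "Segawa syndrome",
    "Sepiapterin reductase deficiency",
    "Warburg effect",
    "Glutaminolysis and cancer",
    "Mercaptopurine action pathway",
    "Thioguanine action pathway",
    "Glycine and serine metabolism",
    "AICA-ribosiduria",
    "Adenine phosphoribosyltransferase deficiency (APRT)",
    "Adenosine deaminase deficiency",
    "Lesch–Nyhan Syndrome (LNS)",
    "Mitochondrial DNA depletion syndrome",
)


@dataclass(frozen=True)
class ZSelection:
    """Per-feature Z-scores for one subject and the metabolites they select."""

    sample_id: str
    z: np.ndarray                     # NaN where controls unusable
    direction: np.ndarray             # "up" / "down" / "none" per feature
    selected_features: np.ndarray     # indices with |z| > z_crit
    selected_metabolites: frozenset


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with the standard derived percentages."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both a positive and a negative class are required")

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    def rounded(self) -> dict[str, int]:
        return {
            "sensitivity": round(self.sensitivity),
            "specificity": round(self.specificity),
            "accuracy": round(self.accuracy),
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Sensitivity, specificity and accuracy (percent) from confusion counts."""
    return ConfusionMetrics(tp, fp, tn, fn)


def zscore_select(
    fm: FeatureMatrix,
    sample_id: str,
    control_ids: set[str] | list[str],
    annotations: pd.DataFrame,
    z_crit: float = DEFAULT_Z_CRIT,
    min_controls: int = 3,
) -> ZSelection:
    """Z-score a subject's feature intensities against the control cohort.

    Control mean and sd (sample sd, n−1 denominator) are computed per
    feature from control samples only; a control subject is excluded from
    its own reference statistics (leave-one-out).  Features whose control
    sd is zero are skipped (z = NaN).  Features with |z| > z_crit map
    through accepted annotations to the selected metabolite set (each
    metabolite counted once).
    """
    s_col = fm.sample_index(sample_id)
    ctrl_cols = [fm.sample_index(c) for c in control_ids if c != sample_id]
    if len(ctrl_cols) < min_controls:
        raise ValueError(
            f"{sample_id}: need >= {min_controls} control samples after leave-one-out, "
            f"got {len(ctrl_cols)}"
        )
    ctrl = fm.intensities[:, ctrl_cols]
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    x = fm.intensities[:, s_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[sd == 0] = np.nan
    n_skipped = int((sd == 0).sum())
    if n_skipped:
        logger.info("%s: %d features skipped (zero control sd)", sample_id, n_skipped)

    direction = np.full(fm.n_features, "none", dtype=object)
    direction[np.nan_to_num(z) > z_crit] = "up"
    direction[np.nan_to_num(z) < -z_crit] = "down"
    sel_idx = np.flatnonzero(direction != "none")

    acc = accepted_by_feature(annotations)
    metabolites: set[str] = set()
    for i in sel_idx:
        metabolites |= acc.get(int(i), set())
    return ZSelection(sample_id, z, direction, sel_idx, frozenset(metabolites))


def panel_ids_from_names(pdb: PathwayDB, names: list[str] | tuple[str, ...]) -> list[str]:
    """Map pathway display names to pathway-DB ids (exact match, case-insensitive)."""
    lookup = {n.strip().lower(): pid for pid, n in zip(pdb.pathway_ids, pdb.names)}
    missing = [n for n in names if n.strip().lower() not in lookup]
    if missing:
        raise KeyError(f"pathway names not in database: {missing}")
    return [lookup[n.strip().lower()] for n in names]


def derive_panel(comparison: pd.DataFrame, size: int = PANEL_SIZE) -> list[str]:
    """Top pathways by mean case representation score (a fresh cohort-derived
    panel, as an alternative to the packaged one)."""
    ranked = comparison.sort_values(
        ["mean_case_score", "pathway_id"], ascending=[False, True], kind="stable"
    )
    return list(ranked["pathway_id"].head(size))


def diagnostic_score(profile: pd.DataFrame, panel: list[str]) -> float:
    """D = sum of the panel pathways' representation scores."""
    scores = profile.set_index("pathway_id")["score"]
    missing = [p for p in panel if p not in scores.index]
    if missing:
        raise KeyError(f"panel pathways missing from profile: {missing}")
    return float(scores.loc[list(panel)].sum())


def classify(d: float, threshold: float) -> str:
    """"PD-pattern" iff the diagnostic score strictly exceeds the threshold."""
    return "PD-pattern" if d > threshold else "no-pattern"


def rank_auc(case_values, control_values) -> float:
    """Area under the ROC curve of a score separating cases from controls
    (rank / Mann–Whitney formulation; ties count 1/2)."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2
    return float(u / (x.size * y.size))


def diagnose_cohort(
    fm: FeatureMatrix,
    annotations: pd.DataFrame,
    pdb: PathwayDB,
    groups: dict[str, str],
    panel: list[str] | None = None,
    z_crit: float = DEFAULT_Z_CRIT,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    universe: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Score every subject of a cohort and label it at each threshold.

    Returns (per-subject table, per-subject score profiles).  When ``panel``
    is None the top-20 panel is derived from the cohort's case-mean scores.
    The permutation universe defaults to the annotated universe.
    """
    from .annotate import annotated_universe  # local import to avoid cycle
    from .enrich import compare_groups

    controls = [s for s, g in groups.items() if g == "control"]
    if not controls:
        raise ValueError("diagnosis requires at least one control sample")
    if universe is None:
        universe = annotated_universe(annotations)
    if not universe:
        raise ValueError("empty annotated universe; nothing to project")

    cache = NullCache(universe, pdb, n_draws=n_draws, seed=seed)
    profiles: dict[str, pd.DataFrame] = {}
    selections: dict[str, ZSelection] = {}
    for s in groups:
        zsel = zscore_select(fm, s, controls, annotations, z_crit=z_crit)
        selections[s] = zsel
        n_sel = len(zsel.selected_metabolites)
        null = cache.get(n_sel) if n_sel else None
        profiles[s] = score_profile(
            set(zsel.selected_metabolites), universe, pdb, n_draws, seed, subject_id=s, null=null
        )

    if panel is None:
        panel = derive_panel(compare_groups(profiles, groups, pdb), PANEL_SIZE)

    rows = []
    for s in groups:
        d = diagnostic_score(profiles[s], panel)
        row = {
            "sample_id": s,
            "group": groups[s],
            "n_selected_metabolites": len(selections[s].selected_metabolites),
            "diagnostic_score": d,
        }
        for t in thresholds:
            row[f"label@{t:g}"] = classify(d, t)
        top = profiles[s].sort_values("score", ascending=False).head(5)
        row["top_pathways"] = ";".join(top["pathway_name"])
        rows.append(row)
    return pd.DataFrame(rows), profiles
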