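"""End-to-end orchestration: spectra → features → candidates → annotations
→ per-subject pathway scores and diagnostic labels."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotate, dbsearch, diagnose, enrich, preprocess
from .io_model import MetaboliteDB, PathwayDB, Spectrum
from .preprocess import FeatureMatrix


@dataclass
class StudyResult:
    """Everything a case–control run produces."""

    features: FeatureMatrix
    candidates: pd.DataFrame
    annotations: pd.DataFrame
    comparison: pd.DataFrame          # per-pathway group table (fold, rank-sum p)
    subjects: pd.DataFrame            # per-subject diagnostic table
    profiles: dict[str, pd.DataFrame]
    panel: list[str]


def run_study(
    spectra: list[Spectrum],
    metabolite_db: MetaboliteDB,
    pathway_db: PathwayDB,
    groups: dict[str, str],
    tol: float = preprocess.DEFAULT_TOL,
    standard_mz: float = preprocess.DEFAULT_STANDARD_MZ,
    min_nonzero: int = 10,
    annotation_params: annotate.AnnotationParams | None = None,
    z_crit: float = diagnose.DEFAULT_Z_CRIT,
    thresholds: tuple[float, ...] = diagnose.DEFAULT_THRESHOLDS,
    n_draws: int = enrich.DEFAULT_DRAWS,
    seed: int = 0,
    panel: list[str] | None = None,
) -> StudyResult:
    """Run the full case–control pipeline on in-memory inputs.

    When ``panel`` is None, the 20-pathway diagnostic panel is derived from
    the cohort's case-mean representation scores.
    """
    fm = preprocess.preprocess_spectra(
        spectra, standard_mz=standard_mz, tol=tol, min_nonzero=min_nonzero
    )
    candidates = dbsearch.match_candidates(fm, metabolite_db, tol=tol)
    annotations = annotate.annotate_features(fm, candidates, pathway_db, annotation_params)

    subjects, profiles = diagnose.diagnose_cohort(
        fm, annotations, pathway_db, groups,
        panel=panel, z_crit=z_crit, thresholds=thresholds, n_draws=n_draws, seed=seed,
    )
    comparison = enrich.compare_groups(profiles, groups, pathway_db)
    used_panel = panel if panel is not None else diagnose.derive_panel(comparison)
    return StudyResult(fm, candidates, annotations, comparison, subjects, profiles, used_panel)
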