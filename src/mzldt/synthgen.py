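"""Fully synthetic direct-infusion metabolomics datasets with known truth.

The generator emulates the data structure the pipeline consumes, end to
end: a metabolite table whose neutral masses sit on a 0.02 Da grid in
[80, 900] (so accurate-mass identities are unambiguous), a pathway table,
and one centroided peak list per subject.  Log-intensities follow a latent
pathway-factor model — members of one pathway share a factor at a
configurable correlation, plus independent biological variation and
technical noise — so the correlation assumption the context-driven
annotation exploits holds by construction.  Case subjects have the members
of designated pathways multiplied by an effect size.  Each metabolite is
emitted as one positive-mode adduct peak ([M+H]+/[M+Na]+/[M+K]+), optionally
with a 13C isotopologue at +1.00336 Da of proportional intensity; every
spectrum carries the internal-standard peak (m/z 423.169) scaled by the
sample's global intensity factor, plus unassignable noise peaks kept at
least 0.05 Da away from any true signal.

Mass decoys make annotation non-trivial: for each true metabolite, database
entries are added at grid masses that match the same observed peak through
a *different* adduct (cross-adduct mass coincidence), assigned to random
other pathways.  A mass-only search cannot tell them from the truth; the
biochemical context can.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dbsearch import ADDUCT_OFFSETS
from .io_model import (
    MetaboliteDB,
    PathwayDB,
    SampleManifest,
    Spectrum,
    write_manifest,
    write_metabolite_db,
    write_pathway_db,
    write_peaklist,
)
from .preprocess import DEFAULT_STANDARD_MZ, ISOTOPE_DELTA

MASS_GRID_STEP = 0.02       # Da; guarantees >= 0.02 Da spacing between neutral masses
MASS_LO, MASS_HI = 80.0, 900.0
MIN_PEAK_GAP = 0.011        # Da between distinct emitted m/z, so 0.005-tol alignment never merges
NOISE_CLEARANCE = 0.05      # Da between noise peaks and any true signal


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe the reference fixture: 40 pathways of 8 metabolites,
    20 cases + 20 controls, 2 perturbed pathways at a 3-fold effect.
    Log-intensity model: ln I = mu_m + signal_sd*(sqrt(w) f_pathway +
    sqrt(1-w) g) + noise_sd*e + case effect + sample scale, with
    w = within_pathway_corr the correlation of the biological signal
    component (signal_sd 0.4 ~ 40% biological CV, noise_sd 0.15 ~ technical
    replicate noise).
    """

    n_pathways: int = 40
    metabolites_per_pathway: int = 8
    n_cases: int = 20
    n_controls: int = 20
    perturbed_pathways: tuple[str, ...] = ("P001", "P002")
    effect_size: float = 3.0
    within_pathway_corr: float = 0.8
    signal_sd: float = 0.4
    noise_sd: float = 0.15
    sample_scale_sd: float = 0.25
    n_noise_peaks: int = 150
    adduct_probs: tuple[tuple[str, float], ...] = (("M+H", 0.7), ("M+Na", 0.2), ("M+K", 0.1))
    isotope_prob: float = 0.3
    n_decoys: int = 2
    standard_mz: float = DEFAULT_STANDARD_MZ
    standard_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pathways", "metabolites_per_pathway", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        probs = dict(self.adduct_probs)
        if set(probs) - set(ADDUCT_OFFSETS):
            raise ValueError("adduct_probs keys must be known adducts")
        if any(not 0 <= p <= 1 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError("adduct probabilities must lie in [0,1] and sum to 1")
        if not 0 <= self.isotope_prob <= 1:
            raise ValueError("isotope_prob must be a probability")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not 0 <= self.within_pathway_corr < 1:
            raise ValueError("within_pathway_corr must be in [0, 1)")


@dataclass
class SimResult:
    """Generated dataset plus its ground truth."""

    config: SimConfig
    spectra: list[Spectrum]
    metabolite_db: MetaboliteDB
    pathway_db: PathwayDB
    manifest: SampleManifest
    truth: pd.DataFrame           # one row per metabolite-db record
    groups: dict[str, str]
    sample_scales: dict[str, float]

    def signal_truth(self) -> pd.DataFrame:
        return self.truth[self.truth["kind"] == "signal"]


def _draw_masses(cfg: SimConfig, rng: np.random.Generator):
    """Choose grid masses, adducts and isotope flags with collision-free m/z."""
    n_met = cfg.n_pathways * cfg.metabolites_per_pathway
    n_grid = int(round((MASS_HI - MASS_LO) / MASS_GRID_STEP))
    if n_met * (1 + cfg.n_decoys) > n_grid // 4:
        raise ValueError(
            f"infeasible spacing: {n_met} metabolites (+decoys) exceed the "
            f"[{MASS_LO}, {MASS_HI}] Da grid at {MASS_GRID_STEP} Da"
        )
    adduct_names = [a for a, _ in cfg.adduct_probs]
    adduct_p = np.array([p for _, p in cfg.adduct_probs])

    occupied: set[int] = set()
    emitted_mz: list[float] = [cfg.standard_mz]
    masses, adducts, iso_flags, iso_mzs = [], [], [], []
    tries = 0
    while len(masses) < n_met:
        tries += 1
        if tries > 80 * n_met:
            raise ValueError("infeasible spacing: could not place metabolite masses")
        gi = int(rng.integers(0, n_grid))
        if gi in occupied:
            continue
        mass = MASS_LO + gi * MASS_GRID_STEP
        adduct = adduct_names[int(rng.choice(len(adduct_names), p=adduct_p))]
        has_iso = bool(rng.random() < cfg.isotope_prob)
        amz = mass + ADDUCT_OFFSETS[adduct]
        new_mz = [amz] + ([amz + ISOTOPE_DELTA] if has_iso else [])
        if any(abs(m - e) < MIN_PEAK_GAP for m in new_mz for e in emitted_mz):
            continue
        occupied.add(gi)
        emitted_mz.extend(new_mz)
        masses.append(mass)
        adducts.append(adduct)
        iso_flags.append(has_iso)
        iso_mzs.append(amz + ISOTOPE_DELTA if has_iso else np.nan)
    return np.array(masses), adducts, iso_flags, iso_mzs, occupied, emitted_mz


def _make_decoys(cfg: SimConfig, rng, masses, adducts, occupied):
    """Cross-adduct decoy database entries for each true metabolite.

    A decoy's neutral mass is the true peak's m/z minus a *different*
    adduct offset, so it matches the same observed peak exactly; decoys
    violating the 0.02 Da minimum mass spacing are skipped.
    """
    all_masses = sorted(masses)
    decoys = []  # (mass, matched_via_adduct, true_metabolite_row)
    for m_idx, (mass, a) in enumerate(zip(masses, adducts)):
        feature_mz = mass + ADDUCT_OFFSETS[a]
        others = [b for b in ADDUCT_OFFSETS if b != a]
        rng.shuffle(others)
        placed = 0
        for b in others:
            if placed >= cfg.n_decoys:
                break
            d_mass = feature_mz - ADDUCT_OFFSETS[b]
            if not MASS_LO <= d_mass <= MASS_HI:
                continue
            pos = bisect.bisect_left(all_masses, d_mass)
            near = [all_masses[k] for k in (pos - 1, pos) if 0 <= k < len(all_masses)]
            if any(abs(d_mass - x) < MASS_GRID_STEP for x in near):
                continue  # would violate minimum mass spacing
            all_masses.insert(pos, d_mass)
            decoys.append((d_mass, b, m_idx))
            placed += 1
    return decoys


def simulate_dataset(cfg: SimConfig | None = None, out_dir: str | None = None) -> SimResult:
    """Generate a complete synthetic study; optionally write all input files.

    Reproducible: the same config (including seed) gives byte-identical
    output files.  Written files: one ``<sample_id>.tsv`` peak list per
    subject, ``metabolites.tsv``, ``pathways.tsv``, ``manifest.tsv`` and
    ``truth.tsv``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_met = cfg.n_pathways * cfg.metabolites_per_pathway

    masses, adducts, iso_flags, iso_mzs, occupied, signal_mz = _draw_masses(cfg, rng)
    pathway_of = np.repeat(np.arange(cfg.n_pathways), cfg.metabolites_per_pathway)
    iso_ratio = np.where(iso_flags, rng.uniform(0.05, 0.3, n_met), np.nan)

    decoys = _make_decoys(cfg, rng, masses, adducts, occupied)
    decoy_pathway = []
    for _, _, m_idx in decoys:
        choices = [p for p in range(cfg.n_pathways) if p != pathway_of[m_idx]]
        decoy_pathway.append(int(rng.choice(choices)))

    # databases
    pw_ids = [f"P{p + 1:03d}" for p in range(cfg.n_pathways)]
    pw_names = [f"Synthetic pathway {p + 1:02d}" for p in range(cfg.n_pathways)]
    met_ids = [f"M{i + 1:04d}" for i in range(n_met)]
    decoy_ids = [f"D{i + 1:04d}" for i in range(len(decoys))]
    members: list[set] = [set() for _ in range(cfg.n_pathways)]
    for i, p in enumerate(pathway_of):
        members[p].add(met_ids[i])
    for d, p in zip(decoy_ids, decoy_pathway):
        members[p].add(d)
    pdb = PathwayDB(tuple(pw_ids), tuple(pw_names), tuple(frozenset(m) for m in members))
    db = MetaboliteDB(
        ids=tuple(met_ids + decoy_ids),
        names=tuple([f"Metabolite {i + 1}" for i in range(n_met)]
                    + [f"Decoy {i + 1}" for i in range(len(decoys))]),
        masses=np.concatenate([masses, [d for d, _, _ in decoys]]),
        xrefs=tuple(f"C{90000 + i:05d}" for i in range(n_met + len(decoys))),
    )

    # samples
    case_ids = [f"case{i + 1:02d}" for i in range(cfg.n_cases)]
    ctrl_ids = [f"ctrl{i + 1:02d}" for i in range(cfg.n_controls)]
    sample_ids = case_ids + ctrl_ids
    groups = {s: ("case" if s in case_ids else "control") for s in sample_ids}
    n_samp = len(sample_ids)
    perturbed_idx = np.array([pw_ids.index(p) for p in cfg.perturbed_pathways])
    is_case = np.array([groups[s] == "case" for s in sample_ids])

    # latent-factor log-intensity model
    mu = rng.uniform(np.log(200.0), np.log(5000.0), n_met)
    w = cfg.within_pathway_corr
    f = rng.standard_normal((cfg.n_pathways, n_samp))           # shared pathway factor
    g = rng.standard_normal((n_met, n_samp))                    # independent biological
    e = rng.standard_normal((n_met, n_samp))                    # technical noise
    ln_i = (
        mu[:, None]
        + cfg.signal_sd * (np.sqrt(w) * f[pathway_of] + np.sqrt(1 - w) * g)
        + cfg.noise_sd * e
    )
    perturbed_met = np.isin(pathway_of, perturbed_idx)
    ln_i[np.ix_(perturbed_met, is_case)] += np.log(cfg.effect_size)
    scales = np.exp(rng.normal(0.0, cfg.sample_scale_sd, n_samp))
    ln_i += np.log(scales)[None, :]
    intensity = np.exp(ln_i)

    # noise masses: per sample, uniform, clear of every true signal
    signal_mz_arr = np.sort(np.array(signal_mz))
    spectra = []
    adduct_mz = masses + np.array([ADDUCT_OFFSETS[a] for a in adducts])
    for si, s in enumerate(sample_ids):
        mzs = list(adduct_mz)
        intens = list(intensity[:, si])
        for i in np.flatnonzero(iso_flags):
            mzs.append(iso_mzs[i])
            intens.append(iso_ratio[i] * intensity[i, si])
        mzs.append(cfg.standard_mz)
        intens.append(cfg.standard_intensity * scales[si])
        n_noise = 0
        while n_noise < cfg.n_noise_peaks:
            cand = rng.uniform(50.0, 1000.0, cfg.n_noise_peaks)
            pos = np.searchsorted(signal_mz_arr, cand)
            near_lo = np.abs(cand - signal_mz_arr[np.clip(pos - 1, 0, len(signal_mz_arr) - 1)])
            near_hi = np.abs(signal_mz_arr[np.clip(pos, 0, len(signal_mz_arr) - 1)] - cand)
            ok = cand[np.minimum(near_lo, near_hi) >= NOISE_CLEARANCE]
            take = ok[: cfg.n_noise_peaks - n_noise]
            mzs.extend(take.tolist())
            intens.extend((np.exp(rng.normal(np.log(150.0), 1.0, take.size)) * scales[si]).tolist())
            n_noise += take.size
        spectra.append(Spectrum.from_peaks(s, mzs, intens))

    truth_rows = []
    for i in range(n_met):
        truth_rows.append(
            {
                "metabolite_id": met_ids[i],
                "kind": "signal",
                "pathway_id": pw_ids[pathway_of[i]],
                "neutral_mass": masses[i],
                "adduct": adducts[i],
                "mz": adduct_mz[i],
                "has_isotope": iso_flags[i],
                "isotope_ratio": iso_ratio[i],
                "perturbed": bool(perturbed_met[i]),
            }
        )
    for j, (d_mass, via, m_idx) in enumerate(decoys):
        truth_rows.append(
            {
                "metabolite_id": decoy_ids[j],
                "kind": "decoy",
                "pathway_id": pw_ids[decoy_pathway[j]],
                "neutral_mass": d_mass,
                "adduct": via,
                "mz": np.nan,
                "has_isotope": False,
                "isotope_ratio": np.nan,
                "perturbed": False,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # relative paths keep the written fixture relocatable and seed-reproducible
    paths = tuple(f"{s}.tsv" for s in sample_ids)
    manifest = SampleManifest(tuple(sample_ids), tuple(groups[s] for s in sample_ids), paths)
    result = SimResult(
        cfg, spectra, db, pdb, manifest, truth, groups,
        {s: float(sc) for s, sc in zip(sample_ids, scales)},
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sp, p in zip(spectra, paths):
            write_peaklist(sp, os.path.join(out_dir, p))
        write_metabolite_db(db, os.path.join(out_dir, "metabolites.tsv"))
        write_pathway_db(pdb, os.path.join(out_dir, "pathways.tsv"))
        write_manifest(manifest, os.path.join(out_dir, "manifest.tsv"))
        truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False, float_format="%.6f")
    return result
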