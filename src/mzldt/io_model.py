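"""Domain types and delimited-text readers/writers.

The pipeline consumes four plain-text inputs: per-sample peak lists
(m/z, intensity), a metabolite table (id, name, monoisotopic neutral mass,
cross-reference id), a pathway table (id, name, semicolon-joined member
metabolite ids) and a sample manifest (sample id, case/control group, path
to the sample's peak list).  Files may be tab- or comma-delimited; the
delimiter is sniffed from the first line.  Decimal points only — no locale
commas.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("case", "control")


class PeaklistParseError(ValueError):
    """Raised when a peak-list file contains a non-numeric or malformed row."""


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if first.count("\t") >= first.count(",") else ","


@dataclass(frozen=True)
class Spectrum:
    """One subject's centroided direct-infusion spectrum.

    Peaks are stored as parallel arrays sorted ascending by m/z, with no
    duplicate m/z values (duplicates are merged by intensity sum at load
    time).
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (np.any(mz <= 0) or np.any(np.diff(mz) <= 0)):
            raise ValueError("m/z values must be strictly positive and strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @classmethod
    def from_peaks(cls, sample_id: str, mz: Iterable[float], intensity: Iterable[float]) -> "Spectrum":
        """Build a Spectrum from unsorted peaks, merging duplicate m/z by intensity sum."""
        mz = np.asarray(list(mz), dtype=float)
        inten = np.asarray(list(intensity), dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            merged = np.zeros(uniq.size)
            np.add.at(merged, inverse, inten)
            logger.info("%s: merged %d duplicate m/z rows", sample_id, mz.size - uniq.size)
            mz, inten = uniq, merged
        return cls(sample_id, mz, inten)


def read_peaklist(path: str, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) delimited peak list.

    An optional single header line is skipped.  Duplicate m/z rows are
    merged by intensity sum.  Non-numeric data rows raise
    :class:`PeaklistParseError` naming the offending line.
    """
    delim = _sniff_delimiter(path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) < 2:
                raise PeaklistParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise PeaklistParseError(
                    f"{path}: line {lineno}: non-numeric cell in {parts[:2]!r}"
                ) from None
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise ValueError(f"{path}: no peaks found")
    return Spectrum.from_peaks(sample_id, mzs, intens)


def write_peaklist(spectrum: Spectrum, path: str) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


@dataclass(frozen=True)
class MetaboliteDB:
    """Metabolite records (id, name, neutral monoisotopic mass, xref id),
    kept sorted ascending by neutral mass for binary search."""

    ids: tuple[str, ...]
    names: tuple[str, ...]
    masses: np.ndarray
    xrefs: tuple[str, ...]

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError("neutral masses must be positive")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("metabolite ids must be unique")
        order = np.argsort(masses, kind="stable")
        object.__setattr__(self, "masses", masses[order])
        object.__setattr__(self, "ids", tuple(np.asarray(self.ids, dtype=object)[order]))
        object.__setattr__(self, "names", tuple(np.asarray(self.names, dtype=object)[order]))
        object.__setattr__(self, "xrefs", tuple(np.asarray(self.xrefs, dtype=object)[order]))

    def __len__(self) -> int:
        return len(self.ids)

    def mass_window(self, lo: float, hi: float) -> np.ndarray:
        """Indices of records with neutral mass in [lo, hi] (binary search)."""
        left = int(np.searchsorted(self.masses, lo, side="left"))
        right = int(np.searchsorted(self.masses, hi, side="right"))
        return np.arange(left, right)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "name": self.names, "monoisotopic_mass": self.masses, "xref": self.xrefs}
        )


def read_metabolite_db(path: str) -> MetaboliteDB:
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype={0: str, 1: str, 3: str})
    df.columns = ["id", "name", "monoisotopic_mass", "xref"]
    return MetaboliteDB(
        ids=tuple(df["id"].astype(str)),
        names=tuple(df["name"].astype(str)),
        masses=df["monoisotopic_mass"].to_numpy(dtype=float),
        xrefs=tuple(df["xref"].astype(str)),
    )


def write_metabolite_db(db: MetaboliteDB, path: str) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class PathwayDB:
    """Pathway → member-metabolite-id mapping plus display names."""

    pathway_ids: tuple[str, ...]
    names: tuple[str, ...]
    members: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("pathway ids must be unique")
        if any(len(m) == 0 for m in self.members):
            raise ValueError("every pathway must have at least one member")
        object.__setattr__(self, "members", tuple(frozenset(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.pathway_ids)

    @property
    def index(self) -> dict:
        return {pid: i for i, pid in enumerate(self.pathway_ids)}

    def pathways_of(self) -> dict:
        """metabolite id → set of pathway indices (inverse mapping)."""
        inv: dict = {}
        for i, mem in enumerate(self.members):
            for m in mem:
                inv.setdefault(m, set()).add(i)
        return inv

    def membership_matrix(self, universe: Sequence[str]) -> np.ndarray:
        """Boolean (len(universe) × n_pathways) membership indicator."""
        mat = np.zeros((len(universe), len(self)), dtype=bool)
        for j, mem in enumerate(self.members):
            for i, m in enumerate(universe):
                if m in mem:
                    mat[i, j] = True
        return mat


def read_pathway_db(path: str) -> PathwayDB:
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, header=None, dtype=str, comment=None)
    if df.iloc[0, 0] in ("pathway_id", "id"):
        df = df.iloc[1:]
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (pathway_id, name, members)")
    pids = [str(x) for x in df.iloc[:, 0]]
    if len(set(pids)) != len(pids):
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        raise ValueError(f"{path}: duplicate pathway ids {dupes}")
    members = []
    for pid, cell in zip(pids, df.iloc[:, 2]):
        if pd.isna(cell) or not str(cell).strip():
            raise ValueError(f"{path}: pathway {pid} has no members")
        mem = frozenset(m.strip() for m in str(cell).split(";") if m.strip())
        if not mem:
            raise ValueError(f"{path}: pathway {pid} has no members")
        members.append(mem)
    return PathwayDB(tuple(pids), tuple(str(x) for x in df.iloc[:, 1]), tuple(members))


def write_pathway_db(pdb: PathwayDB, path: str) -> None:
    rows = [
        (pid, name, ";".join(sorted(mem)))
        for pid, name, mem in zip(pdb.pathway_ids, pdb.names, pdb.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class SampleManifest:
    """Sample id → (group, peak-list path) bookkeeping."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = [g for g in self.groups if g not in VALID_GROUPS]
        if bad:
            raise ValueError(f"invalid group labels {sorted(set(bad))}; expected {VALID_GROUPS}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def cases(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == "case"]

    @property
    def controls(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == "control"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups, "path": self.paths})


def read_manifest(path: str) -> SampleManifest:
    """Read a manifest; relative peak-list paths resolve against the
    manifest's own directory."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    df.columns = ["sample_id", "group", "path"]
    base = os.path.dirname(os.path.abspath(path))
    paths = tuple(
        p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"].fillna("")
    )
    return SampleManifest(tuple(df["sample_id"]), tuple(df["group"]), paths)


def write_manifest(manifest: SampleManifest, path: str) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)
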