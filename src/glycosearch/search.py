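"""Open glycan-mass spectral library search.

For every candidate precursor of a query MS/MS spectrum the engine considers
every library entry (targets and decoys alike) whose backbone mass is below
the precursor mass, asks the glycan mass database whether the precursor
delta (precursor neutral mass - backbone mass) is a known glycan mass within
the precursor tolerance, matches query peaks against the library peaks at
the fragment tolerance, and scores the pairing.  GPSMs failing the minimum
matched-peptide-ion requirement are discarded; per candidate the best GPSM
per library entry is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glycans import GlycanMassDB, GlycanMassEntry, find_glycan_candidates
from .library import LibraryEntry, SpectralLibrary
from .spectra import Ms2Spectrum, oxonium_filter, OXONIUM_MARKER

__all__ = ["SearchConfig", "Gpsm", "match_fragments", "score_gpsm",
           "search_spectrum", "run_search", "gpsms_to_table"]


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters; defaults follow common open glycopeptide search
    practice (10 ppm precursor / 20 ppm fragment tolerances, 1% FDR)."""

    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    min_peptide_ions: int = 3
    oxonium_marker: float = OXONIUM_MARKER
    oxonium_tol: float = 0.02
    y_rel_intensity: float = 0.2
    fdr_level: float = 0.01

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_peptide_ions < 1:
            raise ValueError("min matched peptide ions must be >= 1")


@dataclass
class Gpsm:
    """A glycopeptide-spectrum match: one candidate precursor explained as a
    library backbone plus a glycan mass."""

    raw: str
    scan: int
    candidate_index: int
    precursor_mz: float
    charge: int
    neutral_mass: float
    entry: LibraryEntry
    glycan: GlycanMassEntry
    n_peptide_ions: int
    n_y_ions: int
    score: float
    truth_tag: str = ""  # pass-through label used by simulations

    @property
    def motif_class(self) -> str:
        return self.entry.motif_class

    @property
    def decoy(self) -> bool:
        return self.entry.decoy

    @property
    def entrapment(self) -> bool:
        return self.glycan.entrapment

    @property
    def backbone_key(self) -> tuple:
        """Peptide backbone identity: sequence + modifications."""
        return (self.entry.peptide.sequence, self.entry.peptide.modifications)


def match_fragments(
    query: Ms2Spectrum | tuple[np.ndarray, np.ndarray],
    entry: LibraryEntry,
    tol_ppm: float = 20.0,
) -> tuple[list[tuple[int, int]], int, int]:
    """Greedy nearest-neighbour peak matching within ``tol_ppm`` of each
    library peak; each query peak is used at most once.

    Returns (matched (query index, library index) pairs, number of distinct
    annotated b/y fragment positions matched, number of distinct Y-ladder
    indices matched).  Library peaks are visited in m/z order and take the
    closest still-unused query peak inside the tolerance window.
    """
    if isinstance(query, Ms2Spectrum):
        qmz = query.mz
    else:
        qmz = np.asarray(query[0], dtype=float)
    used = np.zeros(len(qmz), dtype=bool)
    pairs: list[tuple[int, int]] = []
    pep_positions: set[tuple[str, int]] = set()
    y_indices: set[int] = set()
    for j in range(len(entry.mz)):
        lib_mz = entry.mz[j]
        tol = tol_ppm * 1e-6 * lib_mz
        lo = int(np.searchsorted(qmz, lib_mz - tol, side="left"))
        hi = int(np.searchsorted(qmz, lib_mz + tol, side="right"))
        best_i, best_d = -1, np.inf
        for i in range(lo, hi):
            if used[i]:
                continue
            d = abs(qmz[i] - lib_mz)
            if d < best_d:
                best_d, best_i = d, i
        if best_i >= 0:
            used[best_i] = True
            pairs.append((best_i, j))
            ann = entry.annotations[j]
            if ann is not None:
                if ann.series in ("b", "y"):
                    pep_positions.add((ann.series, ann.index))
                elif ann.series == "Y":
                    y_indices.add(ann.index)
    return pairs, len(pep_positions), len(y_indices)


def score_gpsm(
    pairs: Sequence[tuple[int, int]],
    query_intensity: np.ndarray,
    entry_intensity: np.ndarray,
) -> float:
    """Square-root-intensity normalized spectral dot product, scaled 0-100.

    score = 100 * sum_matched sqrt(Iq * Ie) / sqrt(sum_q Iq * sum_e Ie);
    invariant to global intensity scaling of either spectrum and equal to 100
    exactly for a self-match.
    """
    tot_q = float(np.sum(query_intensity))
    tot_e = float(np.sum(entry_intensity))
    if tot_e <= 0 or tot_q <= 0 or not len(pairs):
        return 0.0
    s = sum(
        np.sqrt(query_intensity[i] * entry_intensity[j]) for i, j in pairs
    )
    return float(100.0 * s / np.sqrt(tot_q * tot_e))


def search_spectrum(
    spectrum: Ms2Spectrum,
    lib: SpectralLibrary,
    db: GlycanMassDB,
    cfg: SearchConfig = SearchConfig(),
    keep_all: bool = False,
) -> list[Gpsm]:
    """Search one spectrum: every candidate precursor against every library
    entry (targets and decoys) with an admissible backbone mass.

    A library entry is evaluated when the precursor delta to its backbone
    matches at least one glycan mass within the precursor tolerance
    (referenced to the precursor mass).  Per (candidate, entry) the best
    glycan resolves toward the smallest |delta - glycan mass|; per candidate
    only the best-scoring GPSM across entries survives (score ties keep all
    — competing explanations of one precursor are left to FDR/MiniMax).
    The surviving GPSMs are returned sorted by score (descending).
    ``keep_all`` disables the per-candidate competition and returns every
    GPSM passing the minimum-peptide-ion requirement (diagnostics).
    """
    if len(lib) == 0:
        raise ValueError("empty spectral library")
    if len(db) == 0:
        raise ValueError("empty glycan mass database")
    backbones = np.array([e.backbone_mass for e in lib.entries])
    out: list[Gpsm] = []
    for cand in spectrum.candidates:
        cand_gpsms: list[Gpsm] = []
        pmass = cand.neutral_mass
        tol = cfg.precursor_tol_ppm * 1e-6 * pmass
        deltas = pmass - backbones
        # vectorized pre-check: does any glycan mass sit inside each window?
        lo = np.searchsorted(db.masses, deltas - tol, side="left")
        hi = np.searchsorted(db.masses, deltas + tol, side="right")
        candidates_idx = np.nonzero((deltas > 0) & (hi > lo))[0]
        for ei in candidates_idx:
            entry = lib.entries[int(ei)]
            glycans = find_glycan_candidates(
                float(deltas[ei]), pmass, db, cfg.precursor_tol_ppm
            )
            if not glycans:
                continue
            pairs, n_pep, n_y = match_fragments(spectrum, entry, cfg.fragment_tol_ppm)
            if n_pep < cfg.min_peptide_ions:
                continue
            score = score_gpsm(pairs, spectrum.intensity, entry.intensity)
            best = min(glycans, key=lambda g: abs(g.mass - deltas[ei]))
            cand_gpsms.append(
                Gpsm(
                    raw=spectrum.raw,
                    scan=spectrum.scan,
                    candidate_index=cand.index,
                    precursor_mz=cand.mz,
                    charge=cand.charge,
                    neutral_mass=pmass,
                    entry=entry,
                    glycan=best,
                    n_peptide_ions=n_pep,
                    n_y_ions=n_y,
                    score=score,
                )
            )
        if cand_gpsms:
            if keep_all:
                out.extend(cand_gpsms)
            else:
                top = max(g.score for g in cand_gpsms)
                out.extend(g for g in cand_gpsms if g.score == top)
    out.sort(key=lambda g: -g.score)
    return out


def run_search(
    spectra: Sequence[Ms2Spectrum],
    lib: SpectralLibrary,
    db: GlycanMassDB,
    cfg: SearchConfig = SearchConfig(),
) -> tuple[list[Gpsm], dict]:
    """Oxonium prefilter followed by per-spectrum search.

    Returns (all GPSMs, run metadata with spectra-in / spectra-searched /
    GPSM counts).  Deterministic given identical inputs.
    """
    kept, total = oxonium_filter(spectra, cfg.oxonium_marker, cfg.oxonium_tol)
    gpsms: list[Gpsm] = []
    for s in kept:
        gpsms.extend(search_spectrum(s, lib, db, cfg))
    meta = {
        "spectra_in": total,
        "spectra_searched": len(kept),
        "gpsms": len(gpsms),
    }
    return gpsms, meta


def gpsms_to_table(gpsms: Sequence[Gpsm]) -> pd.DataFrame:
    """Flatten GPSMs to the tab-separable report table."""
    rows = []
    for g in gpsms:
        rows.append(
            {
                "raw": g.raw,
                "scan": g.scan,
                "candidate": g.candidate_index,
                "precursor_mz": g.precursor_mz,
                "charge": g.charge,
                "neutral_mass": g.neutral_mass,
                "peptide": g.entry.peptide.sequence,
                "modifications": ";".join(
                    f"{m.position},{m.name}" for m in g.entry.peptide.modifications
                ),
                "glycosite": g.entry.glycosite,
                "protein_site": g.entry.protein_site,
                "proteins": ";".join(g.entry.proteins),
                "motif": g.motif_class,
                "glycan_mass": g.glycan.mass,
                "glycan_compositions": ",".join(
                    c.to_string() for c in g.glycan.compositions
                ),
                "n_peptide_ions": g.n_peptide_ions,
                "n_Y_ions": g.n_y_ions,
                "score": g.score,
                "decoy": int(g.decoy),
                "entrapment": int(g.entrapment),
            }
        )
    return pd.DataFrame(rows)
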