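"""Build a searchable spectral library from identified deglycopeptides.

PNGase F converts a glycosylated Asn to Asp (+0.984016 Da, read as
deamidation by the upstream search), so every identified deglycopeptide
carrying a deamidated Asn inside an N-glycosylation sequon (N-X-S/T/C/V,
X != P) is a candidate backbone for intact-glycopeptide search.  For each
such site the builder:

* removes the introduced deamidation to recover the backbone peptide and its
  neutral mass,
* annotates experimental peaks explained as b/y fragment ions of the
  (deamidated) peptide,
* appends the theoretical Y0-Y5 ladder (peptide + 0..5 core sugars) at a
  fixed relative intensity, and
* generates a mass- and charge-matched decoy by reversing the sequence while
  holding the three sequon residues in place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    DEAMIDATION,
    Modification,
    ModifiedPeptide,
    fragment_ions,
    glyco_y_ladder,
)
from .spectra import DeglycoPsm, Ms2Spectrum

__all__ = [
    "MOTIF_CLASSES",
    "PeakAnnotation",
    "LibraryConfig",
    "LibraryEntry",
    "SpectralLibrary",
    "motif_class_at",
    "filter_motif_psms",
    "build_entry",
    "make_decoy",
    "build_library",
    "write_library",
    "read_library",
]

MOTIF_CLASSES = ("NXS", "NXT", "NXC", "NXV")
_SEQUON_THIRD = {"S": "NXS", "T": "NXT", "C": "NXC", "V": "NXV"}


@dataclass(frozen=True)
class PeakAnnotation:
    """Fragment-ion label for a library peak: series 'b'/'y' (peptide ions)
    or 'Y' (glycan-retaining ladder), 1-based ion index (0 for Y0), charge."""

    series: str
    index: int
    charge: int

    def to_string(self) -> str:
        return f"{self.series}{self.index}/{self.charge}"

    @classmethod
    def from_string(cls, text: str) -> "PeakAnnotation":
        label, charge = text.split("/")
        series = "Y" if label.startswith("Y") else label[0]
        return cls(series, int(label[len(series):]), int(charge))


@dataclass(frozen=True)
class LibraryConfig:
    """Library-construction parameters.

    fragment_tol is the b/y annotation tolerance in Da; y_rel_intensity the
    relative intensity (vs the base peak) of the appended Y ions; theta is an
    opaque pass-through scoring parameter kept at 0 and currently unused.
    """

    fragment_tol: float = 0.02
    fragment_charges: tuple[int, ...] = (1, 2)
    y_charges: tuple[int, ...] = (1, 2)
    y_rel_intensity: float = 0.2
    keep_all_duplicates: bool = False
    theta: float = 0.0


@dataclass
class LibraryEntry:
    entry_id: int
    peptide: ModifiedPeptide  # backbone: glycosite deamidation removed
    glycosite: int  # 0-based index within the peptide
    motif_class: str
    proteins: tuple[str, ...]
    protein_site: int  # protein-level glycosite position (0-based)
    backbone_mass: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    annotations: list[PeakAnnotation | None]
    decoy: bool = False
    pair_id: int | None = None  # the paired decoy/target entry

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.annotations)):
            raise ValueError("peak arrays and annotations must share length")
        self._sort_peaks()
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")

    def _sort_peaks(self):
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.annotations = [self.annotations[i] for i in order]

    @property
    def deamidated_peptide(self) -> ModifiedPeptide:
        """The library form: backbone + deamidation at the glycosite."""
        return self.peptide.with_modification(
            Modification(self.glycosite, "Deamidated", DEAMIDATION)
        )

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry]
    config: LibraryConfig = field(default_factory=LibraryConfig)

    def __post_init__(self):
        targets = sum(not e.decoy for e in self.entries)
        decoys = len(self.entries) - targets
        if targets != decoys:
            raise ValueError(f"decoy count {decoys} != target count {targets}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def targets(self) -> list[LibraryEntry]:
        return [e for e in self.entries if not e.decoy]


def motif_class_at(sequence: str, site: int) -> str | None:
    """Motif class of an N at ``site``, or None if the N-X-S/T/C/V (X != P)
    sequon is absent or runs off the peptide."""
    if site + 2 >= len(sequence) or sequence[site] != "N":
        return None
    if sequence[site + 1] == "P":
        return None
    return _SEQUON_THIRD.get(sequence[site + 2])


def filter_motif_psms(
    psms: Iterable[DeglycoPsm],
) -> list[tuple[DeglycoPsm, int, str]]:
    """Keep deamidated-Asn sites inside an N-glycosylation sequon.

    Emits one (psm, glycosite index, motif class) record per qualifying
    deamidated site; a deamidated N too close to the C terminus to show its
    sequon is skipped (context unknown).
    """
    out = []
    for psm in psms:
        seq = psm.peptide.sequence
        for mod in psm.peptide.modifications:
            if mod.name != "Deamidated" or not isinstance(mod.position, int):
                continue
            if seq[mod.position] != "N":
                continue
            cls = motif_class_at(seq, mod.position)
            if cls is not None:
                out.append((psm, mod.position, cls))
    return out


def _annotate_by_ions(
    mz: np.ndarray,
    peptide: ModifiedPeptide,
    tol: float,
    charges: Sequence[int],
) -> list[PeakAnnotation | None]:
    """Nearest-theoretical-ion annotation of experimental peaks.

    Each peak takes the closest theoretical b/y ion within ``tol`` Da; ties
    are broken toward the lower series index (b before y at equal index).
    """
    theo = fragment_ions(peptide, ("b", "y"), charges)
    # sort candidate ions by (index, series) so ties resolve deterministically
    theo.sort(key=lambda t: (t[1], t[0], t[2]))
    annotations: list[PeakAnnotation | None] = [None] * len(mz)
    best = np.full(len(mz), np.inf)
    for series, index, charge, ion_mz in theo:
        i = int(np.searchsorted(mz, ion_mz))
        for j in (i - 1, i):
            if 0 <= j < len(mz):
                d = abs(mz[j] - ion_mz)
                if d <= tol and d < best[j]:
                    best[j] = d
                    annotations[j] = PeakAnnotation(series, index, charge)
    return annotations


def build_entry(
    psm: DeglycoPsm,
    site: int,
    spectrum: Ms2Spectrum,
    cfg: LibraryConfig = LibraryConfig(),
    entry_id: int = 0,
) -> LibraryEntry:
    """Turn one identified deglycopeptide spectrum into a library entry.

    The glycosite's introduced deamidation is removed to recover the backbone
    (backbone mass = precursor-implied neutral mass - 0.984016); experimental
    peaks explained as b/y ions of the deamidated peptide are annotated within
    ``cfg.fragment_tol``; the theoretical Y0-Y5 ladder is appended at
    ``cfg.y_rel_intensity`` times the base-peak intensity.
    """
    cls = motif_class_at(psm.peptide.sequence, site)
    if cls is None:
        raise ValueError(f"position {site} of {psm.peptide.sequence} is not a sequon N")
    backbone = psm.peptide.without_modification(site, "Deamidated")
    cand = spectrum.candidates[0]
    backbone_mass = cand.neutral_mass - DEAMIDATION
    annotations = _annotate_by_ions(
        spectrum.mz, psm.peptide, cfg.fragment_tol, cfg.fragment_charges
    )
    base = float(spectrum.intensity.max()) if len(spectrum) else 1.0
    y_mz, y_int, y_ann = [], [], []
    for idx, z, mz in glyco_y_ladder(backbone_mass, cfg.y_charges):
        y_mz.append(mz)
        y_int.append(cfg.y_rel_intensity * base)
        y_ann.append(PeakAnnotation("Y", idx, z))
    return LibraryEntry(
        entry_id=entry_id,
        peptide=backbone,
        glycosite=site,
        motif_class=cls,
        proteins=psm.proteins,
        protein_site=psm.site_offset + site,
        backbone_mass=backbone_mass,
        charge=cand.charge,
        mz=np.concatenate([spectrum.mz, np.asarray(y_mz)]),
        intensity=np.concatenate([spectrum.intensity, np.asarray(y_int)]),
        annotations=annotations + y_ann,
    )


def _reversal_permutation(n: int, sequon: tuple[int, ...]) -> list[int]:
    """new_position -> old_position map for sequence reversal that holds the
    sequon residues at their original indices."""
    fixed = set(sequon)
    others = [i for i in range(n) if i not in fixed]
    perm = list(range(n))
    for k, pos in enumerate(others):
        perm[pos] = others[len(others) - 1 - k]
    return perm


def make_decoy(entry: LibraryEntry, cfg: LibraryConfig = LibraryConfig()) -> LibraryEntry:
    """Sequon-preserving reversed decoy with the same precursor mass/charge.

    The backbone sequence is reversed with the three sequon residues and the
    C-terminal residue pinned (keeping the enzymatic terminus, so decoys
    reproduce the short C-terminal fragment ions shared by tryptic targets);
    modifications travel with their residues (terminal mods stay terminal).
    Annotated b/y peaks move to the reversed sequence's theoretical m/z
    (same series/index/charge, intensity preserved); all other peaks,
    including the Y0-Y5 ladder, are unchanged.
    """
    if entry.decoy:
        raise ValueError("entry is already a decoy")
    seq = entry.peptide.sequence
    n = len(seq)
    if n < 3:
        raise ValueError("peptide too short to reverse")
    site = entry.glycosite
    perm = _reversal_permutation(n, (site, site + 1, site + 2, n - 1))
    new_seq = "".join(seq[perm[i]] for i in range(n))
    inverse = {old: new for new, old in enumerate(perm)}
    new_mods = tuple(
        m if isinstance(m.position, str) else replace(m, position=inverse[m.position])
        for m in entry.peptide.modifications
    )
    decoy_backbone = ModifiedPeptide(new_seq, new_mods)
    decoy_deamidated = decoy_backbone.with_modification(
        Modification(site, "Deamidated", DEAMIDATION)
    )
    theo = {
        (s, i, z): mz
        for s, i, z, mz in fragment_ions(
            decoy_deamidated, ("b", "y"), cfg.fragment_charges
        )
    }
    new_mz = entry.mz.copy()
    for j, ann in enumerate(entry.annotations):
        if ann is not None and ann.series in ("b", "y"):
            new_mz[j] = theo[(ann.series, ann.index, ann.charge)]
    return LibraryEntry(
        entry_id=-entry.entry_id if entry.entry_id else 0,
        peptide=decoy_backbone,
        glycosite=site,
        motif_class=entry.motif_class,
        proteins=entry.proteins,
        protein_site=entry.protein_site,
        backbone_mass=entry.backbone_mass,
        charge=entry.charge,
        mz=new_mz,
        intensity=entry.intensity.copy(),
        annotations=list(entry.annotations),
        decoy=True,
        pair_id=entry.entry_id,
    )


def build_library(
    psms: Sequence[DeglycoPsm],
    spectra: Sequence[Ms2Spectrum],
    cfg: LibraryConfig = LibraryConfig(),
) -> SpectralLibrary:
    """filter_motif_psms -> build_entry -> make_decoy over all inputs.

    Duplicate (sequence, modifications, glycosite) forms keep the PSM with
    the best score unless ``cfg.keep_all_duplicates``.  Raises if nothing
    survives.
    """
    by_key = {s.key: s for s in spectra}
    selected: dict[object, tuple[DeglycoPsm, int]] = {}
    order: list[object] = []
    missing = 0
    for i, (psm, site, _cls) in enumerate(filter_motif_psms(psms)):
        spec = by_key.get((psm.raw, psm.scan))
        if spec is None:
            missing += 1
            continue
        key = (
            i
            if cfg.keep_all_duplicates
            else (psm.peptide.sequence, psm.peptide.modifications, site)
        )
        if key not in selected:
            selected[key] = (psm, site)
            order.append(key)
        elif psm.score > selected[key][0].score:
            selected[key] = (psm, site)
    if missing:
        warnings.warn(f"skipped {missing} PSM site(s) without a matching spectrum")
    entries: list[LibraryEntry] = []
    eid = 0
    skipped_short = 0
    for key in order:
        psm, site = selected[key]
        eid += 1
        target = build_entry(psm, site, by_key[(psm.raw, psm.scan)], cfg, entry_id=eid)
        try:
            decoy = make_decoy(target, cfg)
        except ValueError:
            skipped_short += 1
            continue
        target.pair_id = decoy.entry_id
        entries.extend([target, decoy])
    if skipped_short:
        warnings.warn(f"skipped {skipped_short} entr(ies) too short for a decoy")
    if not entries:
        raise ValueError("no library entries survived motif filtering")
    return SpectralLibrary(entries, cfg)


def _mods_to_str(p: ModifiedPeptide) -> str:
    return ";".join(f"{m.position},{m.name}" for m in p.modifications)


def write_library(lib: SpectralLibrary, path: str | Path) -> None:
    """One TSV row per entry; peaks as ``mz:intensity:annotation`` triples."""
    rows = []
    for e in lib:
        peaks = ";".join(
            f"{mz:.6f}:{inten:.6f}:{ann.to_string() if ann else '-'}"
            for mz, inten, ann in zip(e.mz, e.intensity, e.annotations)
        )
        rows.append(
            {
                "id": e.entry_id,
                "decoy": int(e.decoy),
                "pair_id": e.pair_id if e.pair_id is not None else "",
                "sequence": e.peptide.sequence,
                "modifications": _mods_to_str(e.peptide),
                "glycosite": e.glycosite,
                "motif": e.motif_class,
                "proteins": ";".join(e.proteins),
                "protein_site": e.protein_site,
                "backbone_mass": f"{e.backbone_mass:.6f}",
                "charge": e.charge,
                "peaks": peaks,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library(path: str | Path, cfg: LibraryConfig = LibraryConfig()) -> SpectralLibrary:
    from .spectra import parse_modifications

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        mz, inten, anns = [], [], []
        for triple in row["peaks"].split(";"):
            m, i, a = triple.rsplit(":", 2)
            mz.append(float(m))
            inten.append(float(i))
            anns.append(None if a == "-" else PeakAnnotation.from_string(a))
        entries.append(
            LibraryEntry(
                entry_id=int(row["id"]),
                peptide=ModifiedPeptide(
                    row["sequence"], parse_modifications(row["modifications"])
                ),
                glycosite=int(row["glycosite"]),
                motif_class=row["motif"],
                proteins=tuple(p for p in row["proteins"].split(";") if p),
                protein_site=int(row["protein_site"]),
                backbone_mass=float(row["backbone_mass"]),
                charge=int(row["charge"]),
                mz=np.array(mz),
                intensity=np.array(inten),
                annotations=anns,
                decoy=bool(int(row["decoy"])),
                pair_id=int(row["pair_id"]) if row["pair_id"] != "" else None,
            )
        )
    return SpectralLibrary(entries, cfg)
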