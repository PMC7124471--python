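"""MS/MS spectrum I/O: a co-elution-aware MGF dialect and deglycopeptide
PSM tables.

Raw-file converters that resolve chimeric isolation windows (pParse-style)
emit one MGF block per candidate precursor, so a single fragmentation event
can appear several times with different PEPMASS/CHARGE lines.  Blocks are
merged back into one :class:`Ms2Spectrum` keyed on (raw file, scan number);
titles follow ``<raw>.<scan>.<scan>.<charge>.<index>``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import PROTON, Modification, ModifiedPeptide, MODIFICATIONS

__all__ = [
    "PrecursorCandidate",
    "Ms2Spectrum",
    "DeglycoPsm",
    "read_mgf",
    "write_mgf",
    "read_psm_table",
    "parse_modifications",
    "oxonium_filter",
    "OXONIUM_MARKER",
    "TITLE_PATTERN",
]

OXONIUM_MARKER = 138.055  # HexNAc oxonium fragment, m/z

TITLE_PATTERN = re.compile(
    r"^(?P<raw>.+?)\.(?P<scan>\d+)\.(?P=scan)\.(?P<charge>\d+)\.(?P<index>\d+)$"
)


@dataclass(frozen=True)
class PrecursorCandidate:
    """One candidate precursor of a fragmentation event."""

    mz: float
    charge: int
    index: int = 0

    @property
    def neutral_mass(self) -> float:
        return (self.mz - PROTON) * self.charge


@dataclass
class Ms2Spectrum:
    """A peak list with one or more co-isolated candidate precursors."""

    raw: str
    scan: int
    candidates: list[PrecursorCandidate]
    mz: np.ndarray
    intensity: np.ndarray
    rt: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must share shape")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if not self.candidates:
            raise ValueError("spectrum needs at least one precursor candidate")

    @property
    def key(self) -> tuple[str, int]:
        return (self.raw, self.scan)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class DeglycoPsm:
    """An identified deglycopeptide spectrum match from an upstream database
    search (already filtered to 1% peptide-level FDR)."""

    spectrum_ref: str  # "<raw>.<scan>"
    peptide: ModifiedPeptide
    proteins: tuple[str, ...]
    score: float = 0.0
    semi_tryptic: bool = False
    site_offset: int = 0  # protein-level position of peptide residue 0 (0-based)

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("PSM needs at least one protein accession")
        object.__setattr__(self, "proteins", tuple(self.proteins))

    @property
    def raw(self) -> str:
        return self.spectrum_ref.rsplit(".", 1)[0]

    @property
    def scan(self) -> int:
        return int(self.spectrum_ref.rsplit(".", 1)[1])


def read_mgf(
    path: str | Path, title_pattern: re.Pattern = TITLE_PATTERN
) -> list[Ms2Spectrum]:
    """Read an MGF file, merging blocks that share (raw, scan) into one
    spectrum with multiple precursor candidates.

    Spectrum order follows the first appearance of each (raw, scan); blocks
    with no parseable PEPMASS/CHARGE are skipped with a warning, and a title
    that does not match the dialect is treated as its own scan.
    """
    merged: dict[tuple[str, int], Ms2Spectrum] = {}
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for fallback_scan, block in enumerate(reader):
            params = block["params"]
            title = str(params.get("title", "")).strip()
            pep = params.get("pepmass")
            charge = params.get("charge")
            if pep is None or charge is None:
                skipped += 1
                continue
            mz0 = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
            z = int(charge[0])
            m = title_pattern.match(title)
            if m:
                raw, scan, idx = m["raw"], int(m["scan"]), int(m["index"])
            else:
                raw, scan, idx = (title or "scan"), -(fallback_scan + 1), 0
            cand = PrecursorCandidate(mz=float(mz0), charge=z, index=idx)
            rt = params.get("rtinseconds")
            rt = float(rt) / 60.0 if rt is not None else None
            key = (raw, scan)
            if key in merged:
                merged[key].candidates.append(cand)
            else:
                merged[key] = Ms2Spectrum(
                    raw=raw,
                    scan=scan,
                    candidates=[cand],
                    mz=block["m/z array"],
                    intensity=block["intensity array"],
                    rt=rt,
                )
    if skipped:
        warnings.warn(f"skipped {skipped} MGF block(s) lacking PEPMASS/CHARGE")
    return list(merged.values())


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> int:
    """Write spectra as one BEGIN IONS block per precursor candidate.

    Returns the number of blocks written.  Titles encode raw file, scan,
    charge and candidate index in the dialect :data:`TITLE_PATTERN` reads.
    """
    n = 0
    with open(path, "w") as fh:
        for s in spectra:
            for cand in s.candidates:
                fh.write("BEGIN IONS\n")
                fh.write(f"TITLE={s.raw}.{s.scan}.{s.scan}.{cand.charge}.{cand.index}\n")
                fh.write(f"PEPMASS={cand.mz:.6f}\n")
                fh.write(f"CHARGE={cand.charge}+\n")
                if s.rt is not None:
                    fh.write(f"RTINSECONDS={s.rt * 60.0:.3f}\n")
                for mz, inten in zip(s.mz, s.intensity):
                    fh.write(f"{mz:.5f} {inten:.4f}\n")
                fh.write("END IONS\n")
                n += 1
    return n


_MOD_RE = re.compile(r"^\s*(?P<pos>N-term|C-term|\d+)\s*,\s*(?P<name>[^;]+?)\s*$")


def parse_modifications(text: str) -> tuple[Modification, ...]:
    """Parse ``position,name;position,name;...`` modification syntax.

    Positions are 0-based residue indices or the tags N-term/C-term; names
    must appear in :data:`glycosearch.chem.MODIFICATIONS` (case-insensitive),
    which supplies the delta mass.
    """
    text = (text or "").strip()
    if not text:
        return ()
    lower = {k.lower(): (k, v[0]) for k, v in MODIFICATIONS.items()}
    mods = []
    for part in text.split(";"):
        if not part.strip():
            continue
        m = _MOD_RE.match(part)
        if not m:
            raise ValueError(f"malformed modification record {part!r}")
        name_key = m["name"].strip().lower()
        if name_key not in lower:
            raise ValueError(f"unknown modification name {m['name'].strip()!r}")
        canonical, delta = lower[name_key]
        pos: int | str = m["pos"] if m["pos"] in ("N-term", "C-term") else int(m["pos"])
        mods.append(Modification(position=pos, name=canonical, delta=delta))
    return tuple(mods)


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "spectrum": "spectrum",
    "sequence": "sequence",
    "modifications": "modifications",
    "proteins": "proteins",
    "score": "score",
    "context": "context",
    "site_offset": "site_offset",
}


def _semi_tryptic(context: str, sequence: str) -> bool:
    """Semi-tryptic call from a ``X.PEPTIDE.Z`` protein-context string:
    the N terminus is tryptic when the preceding residue is K/R (or the
    protein terminus '-'), the C terminus when the peptide ends in K/R or
    abuts the protein C terminus."""
    before, after = "-", "-"
    if context:
        parts = context.split(".")
        if len(parts) == 3:
            before, after = parts[0] or "-", parts[2] or "-"
    nterm_ok = before in ("K", "R", "-")
    cterm_ok = sequence[-1] in ("K", "R") or after == "-"
    return not (nterm_ok and cterm_ok)


def read_psm_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> tuple[list[DeglycoPsm], int]:
    """Read a tab-separated deglycopeptide PSM table.

    Returns (psms, n_rejected).  Rows whose modification string cannot be
    parsed are rejected (counted, not fatal); a missing mapped column for the
    required fields is a hard error naming the column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for field_name in ("spectrum", "sequence", "modifications", "proteins"):
        if cmap[field_name] not in df.columns:
            raise ValueError(f"PSM table is missing required column {cmap[field_name]!r}")
    psms: list[DeglycoPsm] = []
    rejected = 0
    for _, row in df.iterrows():
        try:
            mods = parse_modifications(row[cmap["modifications"]])
            seq = row[cmap["sequence"]].strip()
            context = row.get(cmap["context"], "")
            score = float(row[cmap["score"]]) if cmap["score"] in df.columns else 0.0
            offset = (
                int(row[cmap["site_offset"]])
                if cmap["site_offset"] in df.columns and row[cmap["site_offset"]] != ""
                else 0
            )
            psms.append(
                DeglycoPsm(
                    spectrum_ref=row[cmap["spectrum"]].strip(),
                    peptide=ModifiedPeptide(seq, mods),
                    proteins=tuple(
                        p.strip() for p in row[cmap["proteins"]].split(";") if p.strip()
                    ),
                    score=score,
                    semi_tryptic=_semi_tryptic(context, seq),
                    site_offset=offset,
                )
            )
        except (ValueError, KeyError):
            rejected += 1
    return psms, rejected


def write_psm_table(psms: Sequence[DeglycoPsm], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum": p.spectrum_ref,
                "sequence": p.peptide.sequence,
                "modifications": ";".join(
                    f"{m.position},{m.name}" for m in p.peptide.modifications
                ),
                "proteins": ";".join(p.proteins),
                "score": p.score,
                "context": "",
                "site_offset": p.site_offset,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def oxonium_filter(
    spectra: Sequence[Ms2Spectrum],
    marker_mz: float = OXONIUM_MARKER,
    tol: float = 0.02,
) -> tuple[list[Ms2Spectrum], int]:
    """Keep spectra showing the glycan oxonium marker ion.

    Returns (kept spectra, total seen).  A spectrum is kept when at least one
    peak lies within ``tol`` Da of ``marker_mz`` (default 138.055, the HexNAc
    fragment diagnostic of glycopeptide spectra).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    kept = []
    for s in spectra:
        lo = np.searchsorted(s.mz, marker_mz - tol, side="left")
        hi = np.searchsorted(s.mz, marker_mz + tol, side="right")
        if hi > lo:
            kept.append(s)
    return kept, len(spectra)
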