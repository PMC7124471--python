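"""Glycan mass databases in the H-N-S-G-F(-P) composition format.

An N-glycan mass database is a sorted list of monoisotopic masses, each mass
optionally explained by one or more monosaccharide compositions (isomeric
structures collapse to a single mass).  Records are written one per line as
``H-N-S-G-F[-P]<TAB>mass<TAB>source``; bare-mass lines (mass only, no
composition) are allowed so entrapment databases and modified-glycan masses
(sulfated/phosphorylated sugars) can be represented.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import FUC, HEX, HEXNAC, NEUAC, NEUGC, PENT

__all__ = [
    "GlycanComposition",
    "GlycanMassEntry",
    "GlycanMassDB",
    "parse_glycan_db",
    "read_glycan_db",
    "serialize_glycan_db",
    "write_glycan_db",
    "merge_dbs",
    "generate_entrapment",
    "find_glycan_candidates",
    "ENTRAPMENT_SHIFTS",
]

DEDUP_TOL = 1e-4  # Da; isomers are mass-identical, only float noise matters

_COMPONENT_MASSES = (HEX, HEXNAC, NEUAC, NEUGC, FUC, PENT)
_COMPONENT_KEYS = ("Hex", "HexNAc", "NeuAc", "NeuGc", "Fuc", "Pent")


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts in H-N-S-G-F(-P) order: hexose, N-acetyl-
    hexosamine, N-acetylneuraminic acid, N-glycolylneuraminic acid, fucose
    and (optionally) pentose."""

    hex: int = 0
    hexnac: int = 0
    neuac: int = 0
    neugc: int = 0
    fuc: int = 0
    pent: int = 0

    def __post_init__(self):
        counts = self.as_tuple()
        if any(c < 0 for c in counts):
            raise ValueError("monosaccharide counts must be non-negative")
        if all(c == 0 for c in counts):
            raise ValueError("glycan composition must contain at least one residue")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.hex, self.hexnac, self.neuac, self.neugc, self.fuc, self.pent)

    def as_dict(self) -> dict[str, int]:
        return {k: v for k, v in zip(_COMPONENT_KEYS, self.as_tuple()) if v}

    @property
    def mass(self) -> float:
        return sum(n * m for n, m in zip(self.as_tuple(), _COMPONENT_MASSES))

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        parts = text.strip().split("-")
        if len(parts) not in (5, 6):
            raise ValueError(f"expected 5 or 6 dash-separated counts, got {text!r}")
        try:
            counts = [int(p) for p in parts]
        except ValueError:
            raise ValueError(f"non-integer count in {text!r}") from None
        if len(counts) == 5:
            counts.append(0)
        return cls(*counts)

    def to_string(self) -> str:
        counts = self.as_tuple()
        n = 6 if counts[5] else 5
        return "-".join(str(c) for c in counts[:n])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class GlycanMassEntry:
    """One searchable glycan mass with the compositions that explain it."""

    mass: float
    compositions: tuple[GlycanComposition, ...] = ()
    source: str = ""
    entrapment: bool = False
    modified: bool = False  # sulfate/phosphate/amino/rare-sugar mass, no composition

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("glycan mass must be positive")
        if self.entrapment and self.compositions:
            raise ValueError("entrapment entries carry no composition")
        object.__setattr__(self, "compositions", tuple(self.compositions))


@dataclass
class GlycanMassDB:
    """Sorted, deduplicated glycan mass list supporting binary search."""

    entries: list[GlycanMassEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries = _dedup(sorted(self.entries, key=lambda e: e.mass), DEDUP_TOL)
        self._masses = np.array([e.mass for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return self._masses


def _merge_pair(a: GlycanMassEntry, b: GlycanMassEntry) -> GlycanMassEntry:
    comps = list(a.compositions)
    comps += [c for c in b.compositions if c not in comps]
    return GlycanMassEntry(
        mass=a.mass,
        compositions=tuple(comps),
        source=a.source if a.source == b.source or not b.source
        else (f"{a.source}+{b.source}" if a.source else b.source),
        entrapment=a.entrapment and b.entrapment,
        modified=a.modified or b.modified,
    )


def _dedup(sorted_entries: Sequence[GlycanMassEntry], tol: float) -> list[GlycanMassEntry]:
    out: list[GlycanMassEntry] = []
    for e in sorted_entries:
        if out and abs(e.mass - out[-1].mass) <= tol:
            prev = out[-1]
            if e.entrapment != prev.entrapment:
                # never fold an entrapment mass into a true one
                out.append(e)
                continue
            merged = _merge_pair(prev, e) if not (e.entrapment and prev.entrapment) else prev
            out[-1] = merged
        else:
            out.append(e)
    return out


def parse_glycan_db(
    text: str | Iterable[str], source: str = "", entrapment: bool = False
) -> GlycanMassDB:
    """Parse text records into a :class:`GlycanMassDB`.

    Each non-empty, non-comment line is either a dash-separated composition
    (``5-4-2-0-0`` or with a sixth pentose field), optionally followed by
    tab-separated mass and source fields, or a bare mass value (treated as a
    composition-less modified/entrapment mass).
    """
    if isinstance(text, str):
        lines: Iterable[str] = io.StringIO(text)
    else:
        lines = text
    entries: list[GlycanMassEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        token = fields[0].strip()
        src = fields[2].strip() if len(fields) > 2 else source
        try:
            if "-" in token:
                comp = GlycanComposition.from_string(token)
                entries.append(
                    GlycanMassEntry(
                        comp.mass, (comp,), source=src, entrapment=entrapment
                    )
                )
            else:
                mass = float(token)
                entries.append(
                    GlycanMassEntry(
                        mass,
                        (),
                        source=src,
                        entrapment=entrapment,
                        modified=not entrapment,
                    )
                )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return GlycanMassDB(entries)


def read_glycan_db(path: str | Path, **kw) -> GlycanMassDB:
    return parse_glycan_db(Path(path).read_text().splitlines(), **kw)


def serialize_glycan_db(db: GlycanMassDB) -> str:
    """Inverse of :func:`parse_glycan_db`; one line per (mass, composition)."""
    lines = []
    for e in db:
        if e.compositions:
            for c in e.compositions:
                lines.append(f"{c.to_string()}\t{e.mass:.6f}\t{e.source}")
        else:
            lines.append(f"{e.mass:.6f}\t\t{e.source}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_glycan_db(db: GlycanMassDB, path: str | Path) -> None:
    Path(path).write_text(serialize_glycan_db(db))


def merge_dbs(a: GlycanMassDB, b: GlycanMassDB, dedup_tol: float = DEDUP_TOL) -> GlycanMassDB:
    """Union of two databases; masses closer than ``dedup_tol`` collapse into
    one entry holding all compositions (the redundant-isomer rule)."""
    entries = sorted(list(a.entries) + list(b.entries), key=lambda e: e.mass)
    return GlycanMassDB(_dedup(entries, dedup_tol))


# Entrapment shifts: 1.5 to 14.5 Da on a 1-Da grid.
ENTRAPMENT_SHIFTS = np.arange(1.5, 15.0, 1.0)


def generate_entrapment(
    db: GlycanMassDB,
    seed: int | np.random.Generator = 0,
    min_distance: float = 1.0,
    sign: int = +1,
) -> tuple[GlycanMassDB, int]:
    """Entrapment masses: one per original mass, original + shift with the
    shift drawn uniformly from {1.5, 2.5, ..., 14.5} Da subject to the result
    lying at least ``min_distance`` Da from every original mass.

    Returns the entrapment database and the number of originals skipped
    because no admissible shift existed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    originals = db.masses
    entries: list[GlycanMassEntry] = []
    skipped = 0
    for e in db:
        candidates = list(ENTRAPMENT_SHIFTS)
        chosen = None
        while candidates:
            shift = candidates.pop(rng.integers(len(candidates)))
            m = e.mass + sign * shift
            if m > 0 and np.abs(originals - m).min() >= min_distance:
                chosen = m
                break
        if chosen is None:
            skipped += 1
            continue
        entries.append(GlycanMassEntry(chosen, (), source="entrapment", entrapment=True))
    return GlycanMassDB(entries), skipped


def find_glycan_candidates(
    delta_mass: float,
    reference_mass: float,
    db: GlycanMassDB,
    tol_ppm: float = 10.0,
) -> list[GlycanMassEntry]:
    """All database entries whose mass lies within ``tol_ppm`` (relative to
    ``reference_mass``, i.e. the glycopeptide precursor mass) of the observed
    precursor mass delta.  Binary search over the sorted mass array."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if delta_mass <= 0 or len(db) == 0:
        return []
    tol = tol_ppm * 1e-6 * reference_mass
    masses = db.masses
    lo = int(np.searchsorted(masses, delta_mass - tol, side="left"))
    hi = int(np.searchsorted(masses, delta_mass + tol, side="right"))
    return [db.entries[i] for i in range(lo, hi) if abs(masses[i] - delta_mass) <= tol]
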