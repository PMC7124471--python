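"""Identification summaries and the arithmetic used in result tables.

Accepted GPSMs are rolled up to the four reporting levels used in
glycoproteomics: glycoproteins (distinct accessions), glycosites
(accession + protein-level site), intact glycopeptides (backbone sequence +
modifications + site + glycan mass; charge states deduplicate), and glycan
masses.  Percentages are rounded half-away-from-zero, matching how such
tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence
import warnings

from .search import Gpsm

__all__ = ["IdentificationSummary", "aggregate", "ratio_pct", "pct_increase"]


@dataclass(frozen=True)
class IdentificationSummary:
    glycoproteins: int
    glycosites: int
    glycopeptides: int
    glycan_masses: int

    def as_dict(self) -> dict[str, int]:
        return {
            "glycoproteins": self.glycoproteins,
            "glycosites": self.glycosites,
            "glycopeptides": self.glycopeptides,
            "glycan_masses": self.glycan_masses,
        }


def aggregate(gpsms: Sequence[Gpsm]) -> IdentificationSummary:
    """Distinct-key counting of accepted GPSMs; order-invariant.

    A GPSM without a protein accession is counted at the peptide level only
    (with a warning).  Glycan masses are distinguished at 1e-4 Da.
    """
    proteins: set[str] = set()
    sites: set[tuple[str, int]] = set()
    peptides: set[tuple] = set()
    masses: set[int] = set()
    n_orphans = 0
    for g in gpsms:
        mass_key = round(g.glycan.mass * 1e4)
        masses.add(mass_key)
        peptides.add(
            (
                g.entry.peptide.sequence,
                g.entry.peptide.modifications,
                g.entry.glycosite,
                mass_key,
            )
        )
        if g.entry.proteins:
            for acc in g.entry.proteins:
                proteins.add(acc)
                sites.add((acc, g.entry.protein_site))
        else:
            n_orphans += 1
    if n_orphans:
        warnings.warn(
            f"{n_orphans} GPSM(s) lacked a protein accession; "
            "counted at peptide level only"
        )
    return IdentificationSummary(
        glycoproteins=len(proteins),
        glycosites=len(sites),
        glycopeptides=len(peptides),
        glycan_masses=len(masses),
    )


def _round_half_away(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ratio_pct(n: float, d: float, decimals: int = 1) -> float:
    """round(100 * n / d, decimals) with half-away-from-zero rounding."""
    if d == 0:
        raise ValueError("ratio with zero denominator is undefined")
    return _round_half_away(100.0 * n / d, decimals)


def pct_increase(before: float, after: float, decimals: int = 0) -> float:
    """Percent increase relative to ``before``, rounded half-away-from-zero."""
    if before == 0:
        raise ValueError("percent increase from zero is undefined")
    return _round_half_away(100.0 * (after - before) / before, decimals)
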