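"""Error control for glycopeptide-spectrum matches.

Three stages:

* motif-separated target-decoy FDR — GPSMs are split into the four sequon
  classes (NXS/NXT/NXC/NXV) and a score cutoff with FDR = D/T <= level is
  chosen independently within each class;
* the isotopic-peak (MiniMax) filter — co-reported precursors of one scan
  and charge whose masses differ by multiples of a neutron arise from
  monoisotopic-peak assignment errors; per isotope chain the smallest-m/z
  GPSM is kept for identical backbones and the best-scoring one otherwise;
* entrapment validation — the fraction of accepted GPSMs explained by
  shifted (entrapment) glycan masses, an upper bound on the glycan
  assignment error rate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import NEUTRON_MASS
from .library import MOTIF_CLASSES
from .search import Gpsm

__all__ = [
    "NEUTRON",
    "ClassFdr",
    "FdrSummary",
    "estimate_separate_fdr",
    "minimax_filter",
    "entrapment_validate",
]

NEUTRON = NEUTRON_MASS  # Da; isotopologue spacing used for chain grouping


@dataclass(frozen=True)
class ClassFdr:
    motif_class: str
    decoys: int
    targets: int
    cutoff: float | None
    fdr: float | None


@dataclass(frozen=True)
class FdrSummary:
    level: float
    classes: tuple[ClassFdr, ...]

    def as_dict(self) -> dict:
        return {
            c.motif_class: {
                "D": c.decoys,
                "T": c.targets,
                "cutoff": c.cutoff,
                "fdr": c.fdr,
            }
            for c in self.classes
        }


def _class_cutoff(scores: np.ndarray, decoy: np.ndarray, level: float):
    """Most permissive score cutoff with FDR = D/T <= level.

    Scans candidate cutoffs from the lowest score upward and returns
    (cutoff, D, T, fdr) for the first (smallest) score whose D/T at or above
    it meets the level; None if no cutoff qualifies.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = np.cumsum(decoy[order])
    t = np.cumsum(~decoy[order])
    # at each distinct score (lowest last), counts at-or-above that score
    for i in range(len(s) - 1, -1, -1):
        if i + 1 < len(s) and s[i + 1] == s[i]:
            continue  # not a distinct cutoff; use the last index of the tie
        if t[i] > 0 and d[i] / t[i] <= level:
            return float(s[i]), int(d[i]), int(t[i]), float(d[i] / t[i])
    return None


def estimate_separate_fdr(
    gpsms: Sequence[Gpsm], level: float = 0.01
) -> tuple[list[Gpsm], FdrSummary]:
    """Class-wise target-decoy filtering at FDR = D/T <= ``level``.

    Within each motif class GPSMs are ranked by score; the cutoff is the
    smallest score whose class FDR is at or below the level.  Accepted
    targets (never decoys) are returned together with the per-class summary.
    A class where no cutoff reaches the level accepts nothing.
    """
    by_class: dict[str, list[Gpsm]] = defaultdict(list)
    for g in gpsms:
        by_class[g.motif_class].append(g)
    accepted: list[Gpsm] = []
    summaries = []
    for cls in MOTIF_CLASSES:
        members = by_class.get(cls, [])
        if not members:
            summaries.append(ClassFdr(cls, 0, 0, None, None))
            continue
        scores = np.array([g.score for g in members])
        decoy = np.array([g.decoy for g in members])
        found = _class_cutoff(scores, decoy, level)
        if found is None:
            summaries.append(ClassFdr(cls, 0, 0, None, None))
            continue
        cutoff, d, t, fdr = found
        accepted.extend(
            g for g in members if g.score >= cutoff and not g.decoy
        )
        summaries.append(ClassFdr(cls, d, t, cutoff, fdr))
    return accepted, FdrSummary(level, tuple(summaries))


def _isotope_chains(
    group: list[Gpsm], tol_ppm: float, max_k: int
) -> list[list[int]]:
    """Connected components under the relation |Δmass - k*neutron| <= tol
    for some 1 <= k <= max_k, within one (raw, scan, charge) group."""
    n = len(group)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            dm = abs(group[i].neutral_mass - group[j].neutral_mass)
            tol = tol_ppm * 1e-6 * max(group[i].neutral_mass, group[j].neutral_mass)
            k = round(dm / NEUTRON)
            if 1 <= k <= max_k and abs(dm - k * NEUTRON) <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(i)
    return list(comps.values())


def minimax_filter(
    gpsms: Sequence[Gpsm],
    tol_ppm: float = 10.0,
    max_k: int = 4,
) -> list[Gpsm]:
    """Collapse isotopic-peak GPSM chains to one representative.

    GPSMs of one raw scan sharing a charge state whose precursor masses
    differ by k x 1.00335 Da (k = 1..``max_k``, within ``tol_ppm`` of the
    precursor mass) form a chain.  Per chain the GPSM with the smallest
    precursor m/z is kept when all peptide backbones are identical; the
    highest-scoring GPSM (ties toward smaller m/z) is kept otherwise.
    GPSMs outside any chain pass through untouched (true co-elution).
    Idempotent; input order is preserved among survivors.
    """
    grouped: dict[tuple[str, int, int], list[int]] = defaultdict(list)
    for idx, g in enumerate(gpsms):
        grouped[(g.raw, g.scan, g.charge)].append(idx)
    keep = set()
    for indices in grouped.values():
        group = [gpsms[i] for i in indices]
        for comp in _isotope_chains(group, tol_ppm, max_k):
            if len(comp) == 1:
                keep.add(indices[comp[0]])
                continue
            members = [(indices[c], group[c]) for c in comp]
            backbones = {g.backbone_key for _, g in members}
            if len(backbones) == 1:
                chosen = min(members, key=lambda t: t[1].precursor_mz)
            else:
                chosen = max(
                    members, key=lambda t: (t[1].score, -t[1].precursor_mz)
                )
            keep.add(chosen[0])
    return [g for i, g in enumerate(gpsms) if i in keep]


def entrapment_validate(gpsms: Sequence[Gpsm]) -> dict:
    """Entrapment report over accepted GPSMs searched against an
    originals-plus-entrapment glycan database.

    Returns the entrapment GPSM percentage (100 * entrapment/total) and a
    per-glycan-mass table of GPSM count and median score — the data behind a
    confidence scatter of glycan masses.
    """
    total = len(gpsms)
    entrap = sum(g.entrapment for g in gpsms)
    per_mass: dict[tuple[float, bool], list[float]] = defaultdict(list)
    for g in gpsms:
        per_mass[(g.glycan.mass, g.entrapment)].append(g.score)
    table = pd.DataFrame(
        [
            {
                "glycan_mass": mass,
                "entrapment": int(is_ent),
                "n_gpsms": len(scores),
                "median_score": float(np.median(scores)),
            }
            for (mass, is_ent), scores in sorted(per_mass.items())
        ]
    )
    return {
        "total_gpsms": total,
        "entrapment_gpsms": int(entrap),
        "entrapment_pct": (100.0 * entrap / total) if total else 0.0,
        "per_mass": table,
    }
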