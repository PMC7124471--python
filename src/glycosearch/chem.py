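"""Monoisotopic mass bookkeeping for peptides, glycans and their fragments.

All masses are neutral monoisotopic masses in daltons unless a function says
otherwise.  Amino-acid residue masses and element isotope tables come from
pyteomics (:data:`pyteomics.mass.std_aa_mass`, :data:`pyteomics.mass.nist_mass`);
the handful of constants that the downstream search depends on (proton, water,
deamidation, core monosaccharides) are pinned here explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON",
    "WATER",
    "DEAMIDATION",
    "NEUTRON_MASS",
    "HEX",
    "HEXNAC",
    "FUC",
    "NEUAC",
    "NEUGC",
    "PENT",
    "MONOSACCHARIDE_MASSES",
    "MONOSACCHARIDE_FORMULAS",
    "MODIFICATIONS",
    "ElementalComposition",
    "IsotopePattern",
    "Modification",
    "ModifiedPeptide",
    "peptide_mono_mass",
    "peptide_composition",
    "fragment_ions",
    "glyco_y_ladder",
    "glycopeptide_composition",
    "isotope_distribution",
    "idotp",
]

PROTON = 1.0072765
WATER = 18.010565
DEAMIDATION = 0.984016
NEUTRON_MASS = 1.00335  # isotopologue peak spacing, Da

MONOSACCHARIDE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "Fuc": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
    "NeuGc": {"C": 11, "H": 17, "N": 1, "O": 9},
    "Pent": {"C": 5, "H": 8, "O": 4},
}

# Monosaccharide residue masses (glycosidic-bond residues, i.e. free sugar
# minus water), derived from the formulas so compositions and masses agree
# to machine precision.  Printed values: Hex 162.052824, HexNAc 203.079373,
# Fuc 146.057909, NeuAc 291.095417, NeuGc 307.090331, Pent 132.042259.
MONOSACCHARIDE_MASSES: Mapping[str, float] = {
    name: _pmass.calculate_mass(
        composition=_pmass.Composition(dict(formula))
    )
    for name, formula in MONOSACCHARIDE_FORMULAS.items()
}

HEX = MONOSACCHARIDE_MASSES["Hex"]
HEXNAC = MONOSACCHARIDE_MASSES["HexNAc"]
FUC = MONOSACCHARIDE_MASSES["Fuc"]
NEUAC = MONOSACCHARIDE_MASSES["NeuAc"]
NEUGC = MONOSACCHARIDE_MASSES["NeuGc"]
PENT = MONOSACCHARIDE_MASSES["Pent"]

RESIDUE_MASSES: Mapping[str, float] = dict(_pmass.std_aa_mass)

# Variable modifications observed in serum deglycopeptide open searches:
# name -> (monoisotopic delta in Da, elemental formula delta).  Negative
# formula counts encode atom losses.
MODIFICATIONS: Mapping[str, tuple[float, Mapping[str, int]]] = {
    "Deamidated": (0.984016, {"H": -1, "N": -1, "O": 1}),
    "Oxidation": (15.994915, {"O": 1}),
    "Dioxidation": (31.989829, {"O": 2}),
    "Carbamidomethyl": (57.021464, {"C": 2, "H": 3, "N": 1, "O": 1}),
    "Carbamyl": (43.005814, {"C": 1, "H": 1, "N": 1, "O": 1}),
    "Gln->pyro-Glu": (-17.026549, {"H": -3, "N": -1}),
    "Amidine": (41.026549, {"C": 2, "H": 3, "N": 1}),
    "Formyl": (27.994915, {"C": 1, "O": 1}),
    "Sulfide": (31.972071, {"S": 1}),
}


class ElementalComposition(dict):
    """Counts per chemical element; behaves like a plain dict of int counts.

    Supports addition and integer scaling; zero counts are dropped so two
    compositions describing the same molecule compare equal.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for k in [k for k, v in self.items() if v == 0]:
            del self[k]

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({el: c * n for el, c in self.items()})

    __rmul__ = __mul__

    def mono_mass(self) -> float:
        """Monoisotopic mass from the principal isotope of each element."""
        total = 0.0
        for el, n in self.items():
            iso = _element_isotopes(el)
            total += n * iso[0][0]
        return total


def _element_isotopes(element: str) -> list[tuple[float, float]]:
    """(mass, abundance) pairs for an element, most abundant nuclide first
    in mass-number order starting at the lightest stable isotope."""
    try:
        table = _pmass.nist_mass[element]
    except KeyError:
        raise ValueError(f"no isotope table for element {element!r}") from None
    pairs = [
        (m, ab)
        for num, (m, ab) in sorted(table.items())
        if num != 0 and ab > 0
    ]
    if not pairs:
        raise ValueError(f"no isotope abundances for element {element!r}")
    return pairs


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of the isotopologue peaks M0..Mk-1, summing to 1."""

    abundances: tuple[float, ...]

    def __post_init__(self):
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("isotope pattern needs at least one peak")
        if (a < 0).any():
            raise ValueError("isotope abundances must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("isotope abundances must sum to 1")

    def __len__(self) -> int:
        return len(self.abundances)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)


@dataclass(frozen=True)
class Modification:
    """A localized modification: 0-based residue index (or 'N-term'/'C-term'),
    a name, and its monoisotopic delta mass."""

    position: int | str
    name: str
    delta: float


@dataclass(frozen=True)
class ModifiedPeptide:
    sequence: str
    modifications: tuple[Modification, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue letter {ch!r}")
        object.__setattr__(self, "modifications", tuple(self.modifications))
        seen = set()
        for m in self.modifications:
            if isinstance(m.position, int) and not (0 <= m.position < len(self.sequence)):
                raise ValueError(
                    f"modification position {m.position} outside sequence of "
                    f"length {len(self.sequence)}"
                )
            key = (m.position, m.name)
            if key in seen:
                raise ValueError(f"duplicate modification {m.name} at {m.position}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_modification(self, mod: Modification) -> "ModifiedPeptide":
        return ModifiedPeptide(self.sequence, self.modifications + (mod,))

    def without_modification(self, position: int | str, name: str) -> "ModifiedPeptide":
        kept = tuple(
            m for m in self.modifications
            if not (m.position == position and m.name == name)
        )
        if len(kept) == len(self.modifications):
            raise ValueError(f"no modification {name!r} at position {position}")
        return ModifiedPeptide(self.sequence, kept)


def peptide_mono_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    total = WATER + sum(RESIDUE_MASSES[ch] for ch in p.sequence)
    total += sum(m.delta for m in p.modifications)
    return total


def peptide_composition(p: ModifiedPeptide) -> ElementalComposition:
    """Elemental composition of the peptide including its modifications.

    Every modification must have a known elemental formula in
    :data:`MODIFICATIONS` (matched by name, case-insensitively).
    """
    comp = ElementalComposition({"H": 2, "O": 1})
    for ch in p.sequence:
        comp = comp + dict(_pmass.std_aa_comp[ch])
    lower = {k.lower(): v for k, v in MODIFICATIONS.items()}
    for m in p.modifications:
        entry = lower.get(m.name.lower())
        if entry is None:
            raise ValueError(f"modification {m.name!r} has no known elemental formula")
        comp = comp + entry[1]
    return comp


def fragment_ions(
    p: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    charges: Iterable[int] = (1,),
) -> list[tuple[str, int, int, float]]:
    """Full b/y fragment ladders as (series, index, charge, m/z).

    Indices run 1..n-1.  b_i is the N-terminal fragment of i residues
    (neutral mass = sum of residues + mods on them); y_j the C-terminal
    fragment of j residues (+ water).  m/z = (neutral + z * proton) / z.
    """
    series = set(series)
    charges = sorted(set(charges))
    if not series <= {"b", "y"}:
        raise ValueError(f"unsupported ion series: {series - {'b', 'y'}}")
    if not all(z in (1, 2) for z in charges):
        raise ValueError("fragment charges restricted to 1+ and 2+")
    n = len(p.sequence)
    residue = [RESIDUE_MASSES[ch] for ch in p.sequence]
    mod_at = [0.0] * n
    nterm_delta = cterm_delta = 0.0
    for m in p.modifications:
        if m.position == "N-term":
            nterm_delta += m.delta
        elif m.position == "C-term":
            cterm_delta += m.delta
        else:
            mod_at[m.position] += m.delta
    prefix = np.cumsum([residue[i] + mod_at[i] for i in range(n)])
    out: list[tuple[str, int, int, float]] = []
    for i in range(1, n):
        if "b" in series:
            neutral = prefix[i - 1] + nterm_delta
            for z in charges:
                out.append(("b", i, z, (neutral + z * PROTON) / z))
        if "y" in series:
            neutral = (prefix[n - 1] - prefix[n - 1 - i]) + WATER + cterm_delta
            for z in charges:
                out.append(("y", i, z, (neutral + z * PROTON) / z))
    return out


# Neutral Y-ion offsets above the peptide backbone: the trimannosyl-core
# ladder Y0..Y5 = backbone + {0, N, 2N, 2N+H, 2N+2H, 2N+3H}.
_Y_OFFSETS = (
    0.0,
    HEXNAC,
    2 * HEXNAC,
    2 * HEXNAC + HEX,
    2 * HEXNAC + 2 * HEX,
    2 * HEXNAC + 3 * HEX,
)


def glyco_y_ladder(
    backbone_mass: float, charges: Iterable[int] = (1, 2)
) -> list[tuple[int, int, float]]:
    """Theoretical Y0-Y5 ions for a peptide backbone as (Y-index, charge, m/z)."""
    if backbone_mass <= 0:
        raise ValueError("backbone mass must be positive")
    charges = sorted(set(charges))
    out = []
    for idx, off in enumerate(_Y_OFFSETS):
        neutral = backbone_mass + off
        for z in charges:
            out.append((idx, z, (neutral + z * PROTON) / z))
    return out


def glycopeptide_composition(
    p: ModifiedPeptide, glycan: Mapping[str, int]
) -> ElementalComposition:
    """Elemental composition of an intact glycopeptide.

    ``glycan`` maps monosaccharide names (Hex, HexNAc, Fuc, NeuAc, NeuGc,
    Pent) to counts; glycan residues add their dehydrated formulas on top of
    the peptide composition.
    """
    comp = peptide_composition(p)
    for sugar, n in glycan.items():
        if n == 0:
            continue
        if sugar not in MONOSACCHARIDE_FORMULAS:
            raise ValueError(f"unknown monosaccharide {sugar!r}")
        if n < 0:
            raise ValueError(f"negative count for {sugar!r}")
        comp = comp + ElementalComposition(MONOSACCHARIDE_FORMULAS[sugar]) * n
    return comp


def isotope_distribution(c: Mapping[str, int], k: int = 6) -> IsotopePattern:
    """First ``k`` isotopologue relative abundances of a composition.

    Aggregated (nominal-mass) isotope distribution by iterative convolution of
    per-element isotope abundance vectors, truncated to ``k`` peaks and
    renormalized.  Per-element atom powers use binary exponentiation so large
    glycopeptide compositions stay cheap.
    """
    if k < 1:
        raise ValueError("need at least one isotope peak")
    dist = np.zeros(k)
    dist[0] = 1.0
    for el, n in c.items():
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
        if n == 0:
            continue
        pairs = _element_isotopes(el)
        lightest = pairs[0][0]
        vec = np.zeros(k)
        for m, ab in pairs:
            off = int(round(m - lightest))
            if off < k:
                vec[off] += ab
        power = _convolve_power(vec, n, k)
        dist = np.convolve(dist, power)[:k]
    total = dist.sum()
    if total <= 0:
        raise ValueError("degenerate isotope distribution")
    return IsotopePattern(tuple(dist / total))


def _convolve_power(vec: np.ndarray, n: int, k: int) -> np.ndarray:
    result = np.zeros(k)
    result[0] = 1.0
    base = vec.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:k]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:k]
    return result


def idotp(observed: Sequence[float], theoretical: IsotopePattern | Sequence[float]) -> float:
    """Normalized dot product between an observed isotope envelope and a
    theoretical pattern — the isotope-dot-product used to vet precursor
    assignments.  Scale-invariant; 1.0 iff the vectors are proportional."""
    obs = np.asarray(observed, dtype=float)
    theo = (
        theoretical.as_array()
        if isinstance(theoretical, IsotopePattern)
        else np.asarray(theoretical, dtype=float)
    )
    if obs.shape != theo.shape or obs.size < 2:
        raise ValueError("observed and theoretical vectors must share length >= 2")
    if (obs < 0).any():
        raise ValueError("observed abundances must be non-negative")
    no, nt = np.linalg.norm(obs), np.linalg.norm(theo)
    if no == 0 or nt == 0:
        raise ValueError("cannot compute idotp of an all-zero vector")
    return float(np.clip(obs @ theo / (no * nt), 0.0, 1.0))
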