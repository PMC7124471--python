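# Methods

## Model and procedure

An intact N-glycopeptide precursor of neutral mass M is modeled as
M = M(backbone) + M(glycan), where the backbone is a (semi-)tryptic peptide
carrying a sequon N-X-S/T/C/V (X ≠ P) and the glycan is any mass in an
N-glycan mass database. The search is *open* on the glycan side: no glycan
structure is assigned, only a mass (with the compositions that explain it
reported alongside). HCD fragmentation is assumed to produce peptide b/y
ions (mostly glycan-free), the Y0–Y5 ladder (peptide + 0–5 core sugars), and
low-mass oxonium ions; spectra lacking a peak within 0.02 Da of the 138.055
oxonium marker are not searched.

Library entries come from deglycopeptide identifications: PNGase F converts
glycosylated Asn to Asp, so the library spectrum is of the *deamidated*
peptide. The entry stores the backbone (deamidation removed; backbone mass =
precursor-implied mass − 0.984016), b/y annotations made against the
deamidated peptide's theoretical ladder (nearest ion within 0.02 Da, ties
toward the lower series index), and appended theoretical Y0–Y5 peaks at
charges 1+/2+ with intensity 0.2 × the base peak.

Scoring is a square-root-intensity normalized spectral dot product scaled to
0–100: score = 100 · Σ_matched √(I_q·I_e) / √(Σ I_q · Σ I_e), over greedy
nearest-neighbour peak matches (each query peak used once) at 20 ppm. Any
strictly monotone score would serve equally, because error control is
calibrated by target–decoy competition rather than by the score's absolute
scale.

### Decoys

A decoy reverses the target sequence while pinning (i) the three sequon
residues and (ii) the C-terminal residue at their original positions;
modifications travel with their residues. Annotated b/y peaks move to the
reversed sequence's theoretical m/z; Y ions and unannotated peaks are
untouched, so target and decoy share precursor mass, charge and peak count
exactly. Pinning the C terminus is deliberate: tryptic targets share their
short C-terminal fragments (y1 = K/R for fully tryptic peptides), and decoys
that scramble the terminus systematically under-model those coincidences —
in calibration experiments the empirical FDR of the smallest motif class
exceeded its decoy estimate until the terminus was pinned.

### Search and competition

For each precursor candidate, every library entry (target and decoy) with
backbone mass below the precursor mass is tested; an entry survives when the
precursor delta matches a database glycan mass within 10 ppm *of the
precursor mass* (not of the glycan mass) and at least `min_peptide_ions`
distinct annotated b/y positions match. Per candidate only the best-scoring
GPSM survives (exact score ties are all kept); competing explanations of one
precursor are thus resolved by direct target–decoy competition, and distinct
co-eluting precursors of one scan survive independently. Without this
competition, the sequon+terminus-pinned self-decoy of an entry whose sequon
abuts the C terminus can score high against its own target's spectrum and
inflate class cutoffs.

### Error control

FDR = D/T exactly (no +1 correction), computed independently within each of
the four motif classes; the cutoff is the smallest score whose class FDR is
≤ the level, and a class that never reaches the level accepts nothing.
After FDR filtering, GPSMs of one raw scan and charge whose precursor masses
differ by k·1.00335 Da (k = 1..4, tolerance 10 ppm of the precursor mass,
chains extended transitively) are collapsed: identical backbones keep the
smallest precursor m/z (the monoisotopic pick), different backbones keep the
best score (ties toward smaller m/z). Entrapment validation adds one shifted
mass per true glycan mass — shift drawn uniformly from {1.5, 2.5, …, 14.5}
Da, re-drawn until the result is ≥ 1.0 Da from every true mass — and reports
the fraction of accepted GPSMs landing on entrapment masses. Shifts are
applied as additions by default; a sign option exists because a negative
direction is equally defensible.

## Key parameters

| parameter | default | notes |
|---|---|---|
| precursor tolerance | 10 ppm | of the glycopeptide precursor mass |
| fragment tolerance (search) | 20 ppm | greedy peak matching |
| fragment tolerance (library) | 0.02 Da | b/y annotation during construction |
| min matched peptide ions | 3 | distinct b/y positions; 4 for cleaner data |
| Y-ion relative intensity | 0.2 | vs base peak, appended Y0–Y5 at 1+/2+ |
| oxonium marker | 138.055 m/z, 0.02 Da | prefilter; tolerance matches the library construction tolerance since neither is sharper in practice |
| FDR level | 0.01 | per motif class |
| isotope spacing | 1.00335 Da | chain grouping, k ≤ 4 |
| glycan-mass dedup | 1e-4 Da | isomers are mass-identical; only float noise |
| isotope pattern length | 6 peaks | M0–M5; envelope beyond M5 is negligible at glycopeptide masses |
| theta | 0 | opaque scoring pass-through, documented as unused |

Mass constants: proton 1.0072765, water 18.010565, deamidation 0.984016,
neutron spacing 1.00335 Da. Residue masses and isotope abundances come from
pyteomics' standard tables; monosaccharide residue masses are derived from
their elemental formulas (Hex 162.052824, HexNAc 203.079373, Fuc 146.057909,
NeuAc 291.095417, NeuGc 307.090331, Pent 132.042259).

## The simulator

`glycosearch.simulate` generates the complete study world from one seed:
random proteins assembled from planted sequon-bearing peptides (lengths
8–16, motif mixture 42/42/10/6% over NXS/NXT/NXC/NXV, 45% semi-tryptic), a
glycan database of core-containing compositions (150 masses by default, half
of them accompanied by a +1.00335 Da composition-less satellite standing in
for near-isobaric modified glycans — these are what make isotopologue
mispicks explainable and the MiniMax filter exercisable), deglycopeptide
library spectra (full 1+ b/y ladder of the deamidated peptide, log-normal
intensities μ=0 σ=1, 3 ppm fragment jitter, 25 uniform noise peaks, 1 ppm
precursor jitter), and intact query spectra (backbone b/y, Y0–Y5 at 1+/2+,
oxonium ions, noise; charges 2–4). Per query scan: 15% probability of a
co-eluting second glycopeptide (extra candidate + its peaks) and 10%
probability of a monoisotopic mispick (+1 or +2 neutron candidate). The
default study conditions are 500 true glycopeptides plus 500 library-absent
negative-control spectra.

What the simulator does **not** emulate: chimeric fragment interference
beyond simple peak union, charge-state envelopes and deisotoping artifacts,
retention-time structure, intensity correlation between replicate spectra of
one peptide, real glycan biosynthetic structure, and real spectral noise
(Poisson/electronic). Passing calibration tests therefore shows the
*pipeline logic* is sound — decoys calibrate the score distribution of
false matches under these conditions — not that real-data FDR is exactly
nominal.

One physical subtlety is retained deliberately: query b/y ions are emitted
at the unmodified (Asn) backbone positions while library spectra are of the
deamidated form, so site-spanning fragments sit 0.984 Da apart and never
match. This mirrors the real cost of searching intact glycopeptides against
a deglycopeptide library; identifications rest on non-site fragments and the
Y ladder.

## Numerical and design choices

* Duplicate (peptide, modifications, site) library forms keep the
  best-scoring PSM's spectrum; a `keep_all_duplicates` option exists.
* A peptide with several deamidated sequons yields one entry per site, each
  removing only its own site's deamidation.
* Ties in glycan candidate selection for one entry resolve toward the
  smallest |Δ − glycan mass|.
* `estimate_separate_fdr` scans distinct scores from the most permissive
  upward and takes the first admissible cutoff; monotonization (q-values) is
  intentionally not applied, keeping the printed D/T rule exact.
* Entrapment masses never merge with true masses during database dedup.
* Degenerate inputs: empty charge set → empty Y ladder; zero-length chains
  pass MiniMax untouched; a motif class with zero targets reports an empty
  acceptance; an all-zero observed envelope is rejected by idotp.
* The decoy of a peptide whose pinned positions cover the whole sequence
  (e.g. a 3-residue sequon-only peptide) equals its target; such entries are
  vanishingly rare in practice and are kept rather than special-cased.

## Problem sizes

The test suite runs the full pipeline at 500 + 500 spectra for ten seeds
(the default study conditions) for the calibration checks, smaller worlds
(30–120 glycopeptides) for unit and integration tests, and exhaustive
small-composition enumeration (≤ 10 atoms over C/H/N/O/S) as the isotope
oracle. `scripts/acceptance.py` uses the same ten-seed study conditions.

## Known limitations

* Glycan identification is mass-level only; isomeric compositions and
  structures are reported together, never distinguished.
* The score is not the published score of any existing engine; absolute
  score values are not comparable across tools, only the decoy-calibrated
  acceptance is.
* ETD/EThcD fragmentation, a/c/x/z ions, fine isotope structure and
  averagine approximations are out of scope.
* MS1 quantitation is limited to the theoretical isotope pattern + idotp
  primitives; no XIC extraction is provided.
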