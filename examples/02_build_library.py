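"""Build a spectral library from simulated deglycopeptide identifications.

Shows sequon filtering, Y-ion augmentation and sequon-preserving decoy
generation on a small synthetic data set.
"""

from glycosearch import SimConfig, build_library
from glycosearch.simulate import (
    make_glycan_db,
    simulate_glycoproteome,
    simulate_library_spectra,
)

cfg = SimConfig(seed=42, n_glycopeptides=25, n_negative=0)
rng = cfg.rng()
db = make_glycan_db(cfg, rng)
_proteins, truth = simulate_glycoproteome(cfg, rng, db)
psms, spectra = simulate_library_spectra(truth, cfg, rng)

library = build_library(psms, spectra)
targets = library.targets
print(f"deglycopeptide PSMs in     : {len(psms)}")
print(f"library entries            : {len(library)} "
      f"({len(targets)} targets + {len(library) - len(targets)} decoys)")

t = targets[0]
d = next(e for e in library if e.decoy and e.pair_id == t.entry_id)
s = t.glycosite
print(f"target  : {t.peptide.sequence}  site {s}  motif {t.motif_class}  "
      f"backbone {t.backbone_mass:.4f} Da  peaks {len(t)}")
print(f"decoy   : {d.peptide.sequence}  site {s}  motif {d.motif_class}  "
      f"backbone {d.backbone_mass:.4f} Da  peaks {len(d)}")
print("(the decoy reverses the sequence but pins the sequon and C terminus,")
print(" so precursor mass, charge and peak count are identical to the target)")
n_y = sum(1 for a in t.annotations if a is not None and a.series == "Y")
print(f"Y ions appended per entry  : {n_y} (Y0-Y5 at charges 1+ and 2+)")
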