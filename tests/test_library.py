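"""Spectral library construction: sequon filtering, Y augmentation, decoys."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycosearch.chem import (
    DEAMIDATION,
    Modification,
    ModifiedPeptide,
    fragment_ions,
    peptide_mono_mass,
    PROTON,
)
from glycosearch.library import (
    LibraryConfig,
    build_entry,
    build_library,
    filter_motif_psms,
    make_decoy,
    motif_class_at,
    read_library,
    write_library,
)
from glycosearch.simulate import (
    SimConfig,
    make_glycan_db,
    simulate_glycoproteome,
    simulate_library_spectra,
)
from glycosearch.spectra import DeglycoPsm, Ms2Spectrum, PrecursorCandidate

SEQUON_RE = re.compile(r"N[^P][STCV]")


def deam_psm(seq, positions, ref="r.1"):
    mods = tuple(Modification(p, "Deamidated", DEAMIDATION) for p in positions)
    return DeglycoPsm(ref, ModifiedPeptide(seq, mods), ("P1",))


def clean_spectrum_for(psm, scan=1, raw="r", charge=2):
    """Noise-free spectrum: the peptide's full 1+ b/y ladder, exact masses."""
    ions = fragment_ions(psm.peptide, ("b", "y"), (1,))
    mz = np.array([m for *_x, m in ions])
    m = peptide_mono_mass(psm.peptide)
    return Ms2Spectrum(
        raw=raw,
        scan=scan,
        candidates=[PrecursorCandidate((m + charge * PROTON) / charge, charge, 0)],
        mz=mz,
        intensity=np.linspace(1.0, 2.0, len(mz)),
    )


class TestMotifFilter:
    def test_nxt_kept(self):
        records = filter_motif_psms([deam_psm("LNGTK", [1])])
        assert [(site, cls) for _p, site, cls in records] == [(1, "NXT")]

    def test_proline_x_dropped(self):
        assert filter_motif_psms([deam_psm("LNPSK", [1])]) == []

    def test_two_sites_two_records(self):
        records = filter_motif_psms([deam_psm("ANVSNGCK", [1, 4])])
        assert [(s, c) for _p, s, c in records] == [(1, "NXS"), (4, "NXC")]

    def test_cterm_site_without_context_skipped(self):
        assert filter_motif_psms([deam_psm("LGTKN", [4])]) == []

    def test_deamidated_q_ignored(self):
        psm = DeglycoPsm(
            "r.1",
            ModifiedPeptide("LQGTK", (Modification(1, "Deamidated", DEAMIDATION),)),
            ("P1",),
        )
        assert filter_motif_psms([psm]) == []

    @given(st.text(alphabet="ACDNPSTVK", min_size=4, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_regex_oracle(self, seq):
        sites = [i for i, c in enumerate(seq) if c == "N"]
        if not sites:
            return
        psm = deam_psm(seq, sites)
        got = {(s, c) for _p, s, c in filter_motif_psms([psm])}
        want = set()
        for s in sites:
            if SEQUON_RE.match(seq, s):
                want.add((s, "NX" + seq[s + 2]))
        assert got == want


class TestBuildEntry:
    def test_y_ladder_added_at_relative_intensity(self):
        psm = deam_psm("ALNGTKR", [2])
        spec = clean_spectrum_for(psm)
        entry = build_entry(psm, 2, spec)
        y_peaks = [
            (a, mz, i)
            for a, mz, i in zip(entry.annotations, entry.mz, entry.intensity)
            if a is not None and a.series == "Y"
        ]
        assert len(y_peaks) == 12  # Y0-Y5 at 1+ and 2+
        base = spec.intensity.max()
        for _a, _mz, inten in y_peaks:
            assert inten == pytest.approx(0.2 * base, abs=0.0)

    def test_backbone_mass_from_precursor(self):
        psm = deam_psm("ALNGTKR", [2])
        spec = clean_spectrum_for(psm)
        entry = build_entry(psm, 2, spec)
        assert entry.backbone_mass + DEAMIDATION == pytest.approx(
            spec.candidates[0].neutral_mass, abs=1e-6
        )
        # and the precursor-implied backbone agrees with the sequence mass
        assert entry.backbone_mass == pytest.approx(
            peptide_mono_mass(entry.peptide), abs=1e-6
        )

    def test_clean_ladder_fully_annotated(self):
        psm = deam_psm("ALNGTKR", [2])
        entry = build_entry(psm, 2, clean_spectrum_for(psm))
        n_by = sum(1 for a in entry.annotations if a is not None and a.series in "by")
        n_y = sum(1 for a in entry.annotations if a is not None and a.series == "Y")
        # every experimental peak (all are exact b/y ions) is annotated
        assert n_by == len(entry) - n_y

    def test_experimental_peaks_not_displaced(self):
        psm = deam_psm("ALNGTKR", [2])
        spec = clean_spectrum_for(psm)
        entry = build_entry(psm, 2, spec)
        assert set(np.round(spec.mz, 6)) <= set(np.round(entry.mz, 6))

    def test_non_sequon_site_rejected(self):
        psm = deam_psm("ALNGTKR", [2])
        with pytest.raises(ValueError):
            build_entry(psm, 0, clean_spectrum_for(psm))


class TestDecoy:
    def entry(self, seq="ALDNGTKER", site=3):
        psm = deam_psm(seq, [site])
        return build_entry(psm, site, clean_spectrum_for(psm))

    def test_same_backbone_mass_and_charge(self):
        t = self.entry()
        d = make_decoy(t)
        assert d.backbone_mass == t.backbone_mass  # exact: same residues
        assert d.charge == t.charge
        assert peptide_mono_mass(d.peptide) == pytest.approx(
            peptide_mono_mass(t.peptide), abs=1e-9
        )

    def test_sequon_held_in_place(self):
        t = self.entry()
        d = make_decoy(t)
        s = t.glycosite
        assert d.peptide.sequence[s : s + 3] == t.peptide.sequence[s : s + 3]
        assert d.glycosite == s and d.motif_class == t.motif_class

    def test_sequence_is_permutation(self):
        t = self.entry()
        d = make_decoy(t)
        assert sorted(d.peptide.sequence) == sorted(t.peptide.sequence)
        assert d.peptide.sequence != t.peptide.sequence

    def test_only_annotated_by_peaks_move(self):
        t = self.entry()
        d = make_decoy(t)
        assert len(d) == len(t)
        t_peaks = {(round(mz, 6), a.to_string() if a else "-")
                   for mz, a in zip(t.mz, t.annotations)}
        d_peaks = {(round(mz, 6), a.to_string() if a else "-")
                   for mz, a in zip(d.mz, d.annotations)}
        moved = {ann for _mz, ann in t_peaks ^ d_peaks}
        assert all(ann[0] in "by" for ann in moved if ann != "-")
        # Y ions and unannotated peaks identical
        t_static = {p for p in t_peaks if not p[1][0] in "by"}
        d_static = {p for p in d_peaks if not p[1][0] in "by"}
        assert t_static == d_static

    def test_modifications_travel_with_residues(self):
        seq = "AMDNGTKER"
        psm = DeglycoPsm(
            "r.1",
            ModifiedPeptide(
                seq,
                (
                    Modification(3, "Deamidated", DEAMIDATION),
                    Modification(1, "Oxidation", 15.994915),
                ),
            ),
            ("P1",),
        )
        t = build_entry(psm, 3, clean_spectrum_for(psm))
        d = make_decoy(t)
        (ox,) = [m for m in d.peptide.modifications if m.name == "Oxidation"]
        assert d.peptide.sequence[ox.position] == "M"

    def test_too_short_rejected(self):
        psm = deam_psm("NGT", [0])
        # site 0 sequon occupies the whole peptide; reversal cannot proceed
        entry = build_entry(psm, 0, clean_spectrum_for(psm))
        d = make_decoy(entry)
        assert d.peptide.sequence == entry.peptide.sequence  # nothing to move


class TestBuildLibrary:
    def test_counts_and_pairing(self, small_cfg):
        rng = small_cfg.rng()
        db = make_glycan_db(small_cfg, rng)
        _p, truth = simulate_glycoproteome(small_cfg, rng, db)
        psms, spectra = simulate_library_spectra(truth, small_cfg, rng)
        lib = build_library(psms, spectra)
        targets = lib.targets
        decoys = [e for e in lib if e.decoy]
        assert len(targets) == len(decoys)
        assert len(targets) <= len(psms)
        by_id = {e.entry_id: e for e in lib}
        for t in targets:
            assert by_id[t.pair_id].pair_id == t.entry_id

    def test_round_trip(self, small_cfg, tmp_path):
        rng = small_cfg.rng()
        db = make_glycan_db(small_cfg, rng)
        _p, truth = simulate_glycoproteome(small_cfg, rng, db)
        psms, spectra = simulate_library_spectra(truth, small_cfg, rng)
        lib = build_library(psms, spectra)
        path = tmp_path / "lib.tsv"
        write_library(lib, path)
        again = read_library(path)
        assert len(again) == len(lib)
        for a, b in zip(lib, again):
            assert a.peptide == b.peptide
            assert a.backbone_mass == pytest.approx(b.backbone_mass, abs=1e-6)
            assert np.allclose(a.mz, b.mz, atol=1e-6)
            assert np.allclose(a.intensity, b.intensity, atol=1e-6)
            assert [x.to_string() if x else "-" for x in a.annotations] == [
                x.to_string() if x else "-" for x in b.annotations
            ]

    def test_duplicates_keep_best_score(self):
        psm_lo = deam_psm("ALNGTKR", [2], ref="r.1")
        psm_hi = DeglycoPsm(
            "r.2", psm_lo.peptide, ("P1",), score=99.0
        )
        spectra = [
            clean_spectrum_for(psm_lo, scan=1),
            clean_spectrum_for(psm_hi, scan=2),
        ]
        lib = build_library([psm_lo, psm_hi], spectra)
        assert len(lib.targets) == 1

    def test_no_survivors_is_error(self):
        psm = deam_psm("LNPSK", [1])  # proline sequon
        with pytest.raises(ValueError):
            build_library([psm], [clean_spectrum_for(psm)])


def test_motif_class_helper_matches_regex():
    for seq in ("NAS", "NPT", "NGT", "NGC", "NGV", "NGA", "QGT"):
        got = motif_class_at(seq, 0)
        want = "NX" + seq[2] if SEQUON_RE.match(seq) else None
        assert got == want
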