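"""Target-decoy FDR, isotopic-peak filtering, entrapment reporting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycosearch.fdr import (
    NEUTRON,
    entrapment_validate,
    estimate_separate_fdr,
    minimax_filter,
)

from conftest import make_gpsm


def fdr_oracle(scores, decoys, level):
    """Exhaustive threshold scan: most permissive cutoff with D/T <= level."""
    best = None
    for cut in sorted(set(scores)):
        d = sum(1 for s, dec in zip(scores, decoys) if s >= cut and dec)
        t = sum(1 for s, dec in zip(scores, decoys) if s >= cut and not dec)
        if t > 0 and d / t <= level:
            best = cut
            break  # ascending scan: first admissible cutoff is most permissive
    return best


class TestSeparateFdr:
    def test_one_percent_exactly(self):
        gpsms = [make_gpsm(score=100 - i, scan=i) for i in range(100)]
        gpsms.append(make_gpsm(score=0.5, scan=999, decoy=True))
        accepted, summary = estimate_separate_fdr(gpsms, level=0.01)
        cls = summary.as_dict()["NXT"]
        assert cls["D"] == 1 and cls["T"] == 100
        assert cls["fdr"] == pytest.approx(0.01)
        assert len(accepted) == 100

    def test_no_decoys_accepts_all_targets(self):
        gpsms = [make_gpsm(score=float(i), scan=i) for i in range(20)]
        accepted, summary = estimate_separate_fdr(gpsms)
        assert len(accepted) == 20
        assert summary.as_dict()["NXT"]["fdr"] == 0.0

    def test_decoys_never_accepted(self):
        gpsms = [make_gpsm(score=50.0, scan=1), make_gpsm(score=90.0, scan=2, decoy=True)]
        accepted, _ = estimate_separate_fdr(gpsms, level=1.0)
        assert all(not g.decoy for g in accepted)

    def test_classes_filtered_independently(self):
        gpsms = [make_gpsm(score=float(100 - i), scan=i, motif_class="NXT")
                 for i in range(50)]
        # one high decoy poisons NXC only
        gpsms += [make_gpsm(score=99.0, scan=200, motif_class="NXC", decoy=True)]
        gpsms += [make_gpsm(score=50.0, scan=201, motif_class="NXC")]
        accepted, summary = estimate_separate_fdr(gpsms, level=0.01)
        assert {g.motif_class for g in accepted} == {"NXT"}
        assert summary.as_dict()["NXC"]["cutoff"] is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_cutoff_matches_threshold_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 200
        scores = np.round(r.uniform(0, 100, n), 1)
        decoys = r.random(n) < 0.3
        gpsms = [
            make_gpsm(score=float(s), scan=i, decoy=bool(d))
            for i, (s, d) in enumerate(zip(scores, decoys))
        ]
        accepted, summary = estimate_separate_fdr(gpsms, level=0.05)
        want_cut = fdr_oracle(scores, decoys, 0.05)
        got_cut = summary.as_dict()["NXT"]["cutoff"]
        assert got_cut == want_cut
        if want_cut is not None:
            want_n = sum(1 for s, d in zip(scores, decoys) if s >= want_cut and not d)
            assert len(accepted) == want_n

    def test_monotone_in_level(self):
        r = np.random.default_rng(4)
        gpsms = [
            make_gpsm(score=float(s), scan=i, decoy=bool(d))
            for i, (s, d) in enumerate(
                zip(r.uniform(0, 100, 300), r.random(300) < 0.2)
            )
        ]
        sizes = []
        for level in (0.001, 0.01, 0.05, 0.2):
            accepted, _ = estimate_separate_fdr(gpsms, level)
            sizes.append(len(accepted))
        assert sizes == sorted(sizes)


def chain_oracle(group, tol_ppm, max_k=4):
    """Exhaustive pairwise chain construction + keep rule."""
    n = len(group)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        dm = abs(group[i].neutral_mass - group[j].neutral_mass)
        tol = tol_ppm * 1e-6 * max(group[i].neutral_mass, group[j].neutral_mass)
        k = round(dm / NEUTRON)
        if 1 <= k <= max_k and abs(dm - k * NEUTRON) <= tol:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u])
        comps.append(sorted(comp))
    keep = []
    for comp in comps:
        if len(comp) == 1:
            keep.extend(comp)
        elif len({group[i].backbone_key for i in comp}) == 1:
            keep.append(min(comp, key=lambda i: group[i].precursor_mz))
        else:
            keep.append(
                max(comp, key=lambda i: (group[i].score, -group[i].precursor_mz))
            )
    return sorted(keep)


class TestMinimax:
    def mk_chain(self, masses, charge=2, backbone="PEP", scan=5, scores=None):
        scores = scores or [50.0] * len(masses)
        return [
            make_gpsm(
                scan=scan,
                charge=charge,
                neutral_mass=m,
                precursor_mz=(m + charge * 1.0072765) / charge,
                backbone_key=(backbone, ()),
                score=s,
            )
            for m, s in zip(masses, scores)
        ]

    def test_identical_backbone_keeps_smallest_mz(self):
        chain = self.mk_chain([2000.0, 2000.0 + NEUTRON, 2000.0 + 2 * NEUTRON])
        kept = minimax_filter(chain)
        assert len(kept) == 1
        assert kept[0].neutral_mass == 2000.0

    def test_different_backbones_keep_highest_score(self):
        a = self.mk_chain([2000.0], backbone="AAA", scores=[40.0])
        b = self.mk_chain([2000.0 + NEUTRON], backbone="BBB", scores=[70.0])
        kept = minimax_filter(a + b)
        assert [g.backbone_key[0] for g in kept] == ["BBB"]

    def test_single_gpsm_unchanged(self):
        g = make_gpsm()
        assert minimax_filter([g]) == [g]

    def test_different_charge_not_chained(self):
        a = self.mk_chain([2000.0], charge=2)
        b = self.mk_chain([2000.0 + NEUTRON], charge=3)
        assert len(minimax_filter(a + b)) == 2

    def test_true_coelution_passes(self):
        # two GPSMs of one scan, masses 50 Da apart: not an isotope chain
        a = self.mk_chain([2000.0], backbone="AAA")
        b = self.mk_chain([2050.0], backbone="BBB")
        assert len(minimax_filter(a + b)) == 2

    def test_idempotent(self):
        r = np.random.default_rng(9)
        gpsms = []
        for scan in range(20):
            base = float(r.uniform(1500, 3000))
            for k in range(int(r.integers(1, 4))):
                gpsms.extend(
                    self.mk_chain(
                        [base + k * NEUTRON],
                        scan=scan,
                        backbone=str(r.integers(0, 2)),
                        scores=[float(r.uniform(0, 100))],
                    )
                )
        once = minimax_filter(gpsms)
        twice = minimax_filter(once)
        assert once == twice

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_chain_oracle(self, seed):
        r = np.random.default_rng(seed)
        group = []
        base = float(r.uniform(1500, 3000))
        for _ in range(int(r.integers(1, 7))):
            k = int(r.integers(0, 5))
            m = base + k * NEUTRON + float(r.uniform(-1e-3, 1e-3))
            group.append(
                make_gpsm(
                    scan=1,
                    charge=2,
                    neutral_mass=m,
                    precursor_mz=(m + 2 * 1.0072765) / 2,
                    backbone_key=(str(r.integers(0, 3)), ()),
                    score=float(np.round(r.uniform(0, 100), 1)),
                )
            )
        kept = minimax_filter(group)
        want = [group[i] for i in chain_oracle(group, 10.0)]
        assert sorted(id(g) for g in kept) == sorted(id(g) for g in want)

    def test_no_isotope_pair_with_same_backbone_survives(self):
        r = np.random.default_rng(2)
        gpsms = []
        for scan in range(30):
            base = float(r.uniform(1500, 3000))
            for k in range(int(r.integers(1, 4))):
                gpsms.extend(
                    self.mk_chain([base + k * NEUTRON], scan=scan, backbone="X")
                )
        kept = minimax_filter(gpsms)
        for a, b in itertools.combinations(kept, 2):
            if (a.raw, a.scan, a.charge) != (b.raw, b.scan, b.charge):
                continue
            if a.backbone_key != b.backbone_key:
                continue
            dm = abs(a.neutral_mass - b.neutral_mass)
            assert not (0.9 < dm < 1.1)


class TestEntrapment:
    def test_fraction_counting(self):
        gpsms = [make_gpsm(scan=i) for i in range(97)]
        gpsms += [
            make_gpsm(scan=100 + i, entrapment=True, glycan_mass=1501.5)
            for i in range(3)
        ]
        rep = entrapment_validate(gpsms)
        assert rep["entrapment_gpsms"] == 3
        assert rep["entrapment_pct"] == pytest.approx(3.0)
        per = rep["per_mass"]
        assert per[per["entrapment"] == 1]["n_gpsms"].sum() == 3

    def test_zero_entrapment(self):
        rep = entrapment_validate([make_gpsm()])
        assert rep["entrapment_pct"] == 0.0

    def test_empty(self):
        rep = entrapment_validate([])
        assert rep["total_gpsms"] == 0 and rep["entrapment_pct"] == 0.0
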