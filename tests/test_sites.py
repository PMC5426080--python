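"""Active-site detection, dihedral angles, state classification, contacts."""

import numpy as np
import pytest

from plpgeom import (RunConfig, classify_state, detect_persulfide,
                     external_dihedral, find_plp_sites, hbond_contacts,
                     internal_dihedral, make_aldimine_model, summarize,
                     triangle_distances)
from plpgeom.sites import DihedralReport, MalformedCofactorError, analyze_model
from plpgeom.structure_io import Atom, Chain, Residue, StructureModel

from conftest import apply_rigid, random_rotation

# Reported per-protomer internal/external angles of the four
# catalytic-intermediate crystals (two protomers each).
TABLE_ROWS = [
    ("NAT", 47.7, None), ("NAT", 45.0, None),
    ("GD", 69.1, -50.2), ("GD", 64.8, -53.6),
    ("IAA", 53.3, -51.4), ("GD", 64.9, -50.0),
    ("PSF", 38.3, None), ("PSF", 50.3, None),
]


class TestFindSites:
    @pytest.mark.parametrize("dialect", ["plp-link", "llp"])
    def test_matches_generator_manifest(self, dialect):
        model, manifest = make_aldimine_model(60.0, state="NAT", dialect=dialect)
        sites = find_plp_sites(model)
        assert len(sites) == 1
        site = sites[0]
        assert site.chain_id == "A"
        assert site.internal_partner is not None
        assert site.internal_covalent
        assert site.external_ligand is None
        assert site.dialect == ("fused" if dialect == "llp" else "linked")
        assert set(site.ring_atoms) == {"N1", "C2", "C3", "C4", "C5", "C6"}
        assert {"P", "O1P", "O2P", "O3P", "O4P"} <= set(site.phosphate_atoms)

    def test_plp_free_model_empty(self):
        m = StructureModel(id="bare", chains=[Chain(id="A", residues=[
            Residue(name="GLY", seq=1, atoms=[
                Atom(1, "CA", "C", "", 1.0, 10.0, np.zeros(3))])])])
        assert find_plp_sites(m) == []

    def test_malformed_ring_raises_naming_residue(self, nat_model):
        model, _ = nat_model
        plp = next(r for c in model.chains for r in c.residues if r.name == "PLP")
        plp.atoms = [a for a in plp.atoms if a.name != "C5"]
        with pytest.raises(MalformedCofactorError, match="PLP401"):
            find_plp_sites(model)

    def test_distorted_ring_bond_raises(self, nat_model):
        model, _ = nat_model
        plp = next(r for c in model.chains for r in c.residues if r.name == "PLP")
        plp.atom("C5").coords += np.array([0.0, -0.8, 0.0])
        with pytest.raises(MalformedCofactorError, match="outside"):
            find_plp_sites(model)


class TestDihedrals:
    @pytest.mark.parametrize("internal", [-150.0, -60.0, 0.0, 45.0, 47.7, 120.0])
    @pytest.mark.parametrize("dialect", ["plp-link", "llp"])
    def test_internal_recovery_including_sign(self, internal, dialect):
        model, _ = make_aldimine_model(internal, state="NAT", dialect=dialect)
        site = find_plp_sites(model)[0]
        assert internal_dihedral(site) == pytest.approx(internal, abs=1e-6)

    @pytest.mark.parametrize("external", [-90.0, -51.0, -10.0, 0.0])
    def test_external_recovery_gem_diamine(self, external):
        model, _ = make_aldimine_model(66.0, external, state="GD", persulfide=True)
        site = find_plp_sites(model)[0]
        assert external_dihedral(site) == pytest.approx(external, abs=1e-6)
        assert site.external_covalent

    def test_external_none_for_internal_aldimine(self, nat_model):
        model, _ = nat_model
        assert external_dihedral(find_plp_sites(model)[0]) is None

    def test_proposed_external_angle_free_ligand(self, iaa_model):
        model, _ = iaa_model
        site = find_plp_sites(model)[0]
        assert not site.external_covalent
        assert external_dihedral(site) == pytest.approx(-51.4, abs=1e-6)

    def test_plane_bond_convention_zero_for_in_plane_bond(self):
        cfg = RunConfig(convention="plane-bond")
        model, _ = make_aldimine_model(0.0, state="NAT")
        site = find_plp_sites(model)[0]
        # a torsion of 0 keeps NZ in the ring plane: elevation angle 0
        assert internal_dihedral(site, cfg) == pytest.approx(0.0, abs=1e-6)

    def test_plane_bond_sign_tracks_torsion_sign(self):
        cfg = RunConfig(convention="plane-bond")
        for tor in (60.0, -60.0):
            model, _ = make_aldimine_model(tor, state="NAT")
            site = find_plp_sites(model)[0]
            val = internal_dihedral(site, cfg)
            assert np.sign(val) == np.sign(tor)


class TestClassification:
    @pytest.mark.parametrize("state,ext,persulfide", [
        ("NAT", None, False), ("GD", -51.0, True), ("GD", -51.0, False),
        ("IAA", -51.4, True), ("IAA", -51.4, False), ("PSF", None, True),
    ])
    def test_states_recovered(self, state, ext, persulfide):
        model, _ = make_aldimine_model(50.0, ext, state=state, persulfide=persulfide)
        site = find_plp_sites(model)[0]
        assert classify_state(site, model) == state

    def test_persulfide_does_not_relabel_gd_or_iaa(self):
        # sulfur transfer precedes ligand release: GD/IAA sites routinely
        # carry the persulfide and must keep their ligand-derived label
        for state, ext in (("GD", -50.0), ("IAA", -51.0)):
            model, _ = make_aldimine_model(60.0, ext, state=state, persulfide=True)
            site = find_plp_sites(model)[0]
            assert detect_persulfide(model, "A") != []
            assert classify_state(site, model) == state

    def test_unknown_when_internal_linkage_broken(self, nat_model):
        model, _ = nat_model
        lys = next(r for c in model.chains for r in c.residues if r.name == "LYS")
        for a in lys.atoms:
            a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        site = find_plp_sites(model)[0]
        assert classify_state(site, model) == "UNKNOWN"

    def test_rigid_motion_leaves_labels_and_angles_unchanged(self):
        rng = np.random.default_rng(17)
        rot = random_rotation(rng)
        trans = rng.normal(scale=20.0, size=3)
        for state, ext, ps in (("NAT", None, False), ("GD", -51.0, True),
                               ("IAA", -51.4, True), ("PSF", None, True)):
            model, _ = make_aldimine_model(58.0, ext, state=state, persulfide=ps)
            moved = apply_rigid(model, rot, trans)
            s0 = find_plp_sites(model)[0]
            s1 = find_plp_sites(moved)[0]
            assert classify_state(s1, moved) == classify_state(s0, model) == state
            assert internal_dihedral(s1) == pytest.approx(internal_dihedral(s0), abs=1e-6)
            if ext is not None:
                assert external_dihedral(s1) == pytest.approx(external_dihedral(s0), abs=1e-6)


class TestPersulfide:
    def test_detected_at_2_05_with_terminal_atom(self, psf_model):
        model, _ = psf_model
        hits = detect_persulfide(model, "A")
        assert len(hits) == 1
        res, s_atom = hits[0]
        assert res.seq == 356
        assert s_atom.element == "S"

    def test_unmodified_cys_not_detected(self, nat_model):
        model, _ = nat_model
        assert detect_persulfide(model, "A") == []

    @pytest.mark.parametrize("d,expected", [(1.85, 0), (1.95, 1), (2.25, 1), (2.4, 0)])
    def test_ss_distance_window(self, d, expected):
        model, _ = make_aldimine_model(45.0, state="PSF", persulfide=True)
        cys = next(r for c in model.chains for r in c.residues if r.name == "CYS")
        sg, sd = cys.atom("SG"), cys.atom("SD")
        direction = (sd.coords - sg.coords) / np.linalg.norm(sd.coords - sg.coords)
        sd.coords = sg.coords + d * direction
        assert len(detect_persulfide(model, "A")) == expected

    def test_absent_chain_gives_empty(self, psf_model):
        model, _ = psf_model
        assert detect_persulfide(model, "Q") == []


class TestHbonds:
    def test_distant_polar_atoms_excluded(self):
        mk = lambda seq, name, el, x: Residue(name="HOH" if el == "O" else "GLY", seq=seq, atoms=[
            Atom(seq, name, el, "", 1.0, 10.0, np.array([x, 0.0, 0.0]))])
        m = StructureModel(id="pair", chains=[Chain(id="A", residues=[
            mk(1, "O", "O", 0.0), mk(2, "O", "O", 5.0)])])
        focus = [m.chains[0].residues[0].atoms[0]]
        assert hbond_contacts(m, focus, cutoff=3.5) == []

    def test_phosphate_partners_found_and_sorted(self, nat_model):
        model, _ = nat_model
        # drop a serine hydroxyl near a phosphate oxygen
        site = find_plp_sites(model)[0]
        o1p = site.phosphate_atoms["O1P"]
        ser = Residue(name="SER", seq=87, atoms=[
            Atom(900, "OG", "O", "", 1.0, 10.0, o1p.coords + np.array([2.7, 0, 0])),
            Atom(901, "CB", "C", "", 1.0, 10.0, o1p.coords + np.array([3.0, 1.2, 0])),
        ])
        model.chains[0].residues.append(ser)
        focus = list(site.phosphate_atoms.values())
        contacts = hbond_contacts(model, focus)
        labels = {label for _, _, label, _ in contacts}
        assert "A/SER87" in labels
        partners = [p.name for _, p, _, _ in contacts]
        assert "CB" not in partners  # carbon is never a donor/acceptor
        dists = [d for _, _, _, d in contacts]
        assert dists == sorted(dists)

    def test_empty_focus_empty_result(self, nat_model):
        model, _ = nat_model
        assert hbond_contacts(model, []) == []

    def test_nonpositive_cutoff_rejected(self, nat_model):
        model, _ = nat_model
        with pytest.raises(ValueError):
            hbond_contacts(model, [model.chains[0].residues[0].atoms[0]], cutoff=0.0)


class TestTriangle:
    def test_manifest_distances_recovered_exactly(self, gd_model):
        model, manifest = gd_model
        site = find_plp_sites(model)[0]
        got = triangle_distances(site)
        for g, e in zip(got, manifest.expected_triangle):
            assert g == pytest.approx(e, abs=1e-9)

    def test_nat_site_has_only_lysine_hydroxyl_distance(self, nat_model):
        model, _ = nat_model
        d1, d2, d3 = triangle_distances(find_plp_sites(model)[0])
        assert d1 is not None and d2 is None and d3 is None


class TestSummarize:
    @staticmethod
    def rows():
        return [DihedralReport("x", chr(65 + i), i_deg, e_deg, st)
                for i, (st, i_deg, e_deg) in enumerate(TABLE_ROWS)]

    def test_pooled_internal_aldimine_statistics(self):
        summ = {s.state: s for s in summarize(self.rows())}
        pooled = summ["NAT and PSF"]
        assert round(pooled.mean_internal, 1) == 45.3
        assert round(pooled.sd_internal, 1) == 5.2
        assert pooled.mean_external is None and pooled.n == 4

    def test_gem_diamine_spread(self):
        summ = {s.state: s for s in summarize(self.rows())}
        gd = summ["GD"]
        assert round(gd.sd_internal, 1) == 2.5
        assert round(gd.sd_external, 1) == 2.0
        assert gd.n == 3

    def test_single_member_group_has_no_sd(self):
        summ = {s.state: s for s in summarize(self.rows())}
        iaa = summ["IAA"]
        assert iaa.n == 1
        assert iaa.sd_internal is None and iaa.sd_external is None
        assert iaa.mean_internal == pytest.approx(53.3)

    def test_unpooled_groups_also_reported(self):
        states = [s.state for s in summarize(self.rows())]
        assert {"NAT", "PSF", "GD", "IAA", "NAT and PSF"} <= set(states)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAnalyzeModel:
    def test_one_row_per_site_with_state(self, gd_model):
        model, _ = gd_model
        rows = analyze_model(model)
        assert len(rows) == 1
        r = rows[0]
        assert (r.protomer, r.state) == ("A", "GD")
        assert r.internal_deg == pytest.approx(66.0, abs=1e-6)
        assert r.external_deg == pytest.approx(-51.0, abs=1e-6)
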