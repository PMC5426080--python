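"""Idealized synthetic structures with analytically known geometry.

Every pipeline stage is testable without downloading crystal structures:
this module builds a PLP cofactor whose pyridine ring, Schiff-base linkage
and surroundings are placed by exact internal-coordinate construction, so
the internal/external dihedral angles, catalytic state, persulfide bond and
triangle distances requested by the caller are recovered by the analysis to
machine precision. The covalent chemistry mirrors the states seen along the
cysteine-desulfurase cycle:

* ``NAT`` — internal aldimine: PLP C4A double-bonded to the lysine NZ.
* ``GD``  — gem-diamine: C4A simultaneously single-bonded to the lysine NZ
  and to the amine nitrogen of an alanine ligand.
* ``IAA`` — internal aldimine with a free (non-bonded) alanine sitting
  3.0 A from C4A at a requested "proposed" external dihedral.
* ``PSF`` — internal aldimine plus a persulfide-modified catalytic
  cysteine (terminal sulfur 2.05 A from SG).

Bond lengths and angles are fixed chemically plausible idealizations (one
table below); they are not refined, since tests compare the pipeline's
output against the generator's manifest rather than against chemistry.

Two PDB dialects are emitted so the reader's both-dialect handling is
exercised: ``"plp-link"`` writes a separate PLP het residue plus a LINK
record to Lys NZ, and ``"llp"`` writes a single fused lysine-PLP residue
with primed atom names (C4', C5', OP1...), as deposited structures do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geom import distance, place_atom
from .structure_io import Atom, AtomRef, Chain, LinkRecord, Residue, StructureModel

__all__ = [
    "FixtureManifest",
    "IDEAL",
    "make_aldimine_model",
    "make_two_sphere_fixture",
    "make_dimer_fixture",
]

STATES = ("NAT", "GD", "IAA", "PSF")

# Idealized internal coordinates (A / degrees).
IDEAL = {
    "ring_bond": 1.39,        # aromatic C-C / C-N
    "c3_o3": 1.36,            # phenolic hydroxyl
    "c4_c4a": 1.46,           # exocyclic Schiff-base carbon
    "c4a_n_double": 1.28,     # aldimine C=N
    "c4a_n_single": 1.47,     # gem-diamine C-N
    "iaa_n_c4a": 3.00,        # free-ligand amine to C4A
    "n_ce": 1.47,             # lysine NZ-CE
    "c_c": 1.52,              # generic sp3 C-C
    "c5_c5a": 1.50,
    "c5a_o4p": 1.43,
    "o4p_p": 1.60,
    "p_o": 1.50,              # phosphate P-O terminal
    "ss": 2.05,               # persulfide S-S
    "cb_sg": 1.81,
    "sp2_angle": 120.0,
    "sp3_angle": 109.5,
}

# Ring atom placement: regular hexagon of side ring_bond in the z=0 plane.
_RING_ORDER = ("N1", "C2", "C3", "C4", "C5", "C6")
_RING_ANGLES = {"N1": 90.0, "C2": 150.0, "C3": 210.0, "C4": 270.0, "C5": 330.0, "C6": 30.0}

# Atom-name dialects: separate PLP residue vs fused LLP residue.
_PLP_NAMES = {"C2A": "C2A", "C4A": "C4A", "C5A": "C5A", "O3": "O3", "P": "P",
              "O4P": "O4P", "O1P": "O1P", "O2P": "O2P", "O3P": "O3P"}
_LLP_NAMES = {"C2A": "C2'", "C4A": "C4'", "C5A": "C5'", "O3": "O3", "P": "P",
              "O4P": "OP4", "O1P": "OP1", "O2P": "OP2", "O3P": "OP3"}


@dataclass
class FixtureManifest:
    """Ground truth for one generated model, against which tests compare."""

    requested_internal_deg: float
    requested_external_deg: float | None
    state: str
    persulfide: bool
    dialect: str
    jitter: float
    atoms: list[tuple[str, str, int, str, tuple[float, float, float]]] = field(default_factory=list)
    expected_state: str = ""
    expected_triangle: tuple[float | None, float | None, float | None] = (None, None, None)

    def to_dict(self) -> dict:
        return {
            "requested_internal_deg": self.requested_internal_deg,
            "requested_external_deg": self.requested_external_deg,
            "state": self.state,
            "persulfide": self.persulfide,
            "dialect": self.dialect,
            "jitter": self.jitter,
            "expected_state": self.expected_state,
            "expected_triangle": list(self.expected_triangle),
            "atoms": [
                {"chain": c, "res_name": rn, "res_seq": rs, "name": an, "coords": list(xyz)}
                for c, rn, rs, an, xyz in self.atoms
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_aldimine_model(
    internal_deg: float,
    external_deg: float | None = None,
    state: str = "NAT",
    persulfide: bool = False,
    jitter: float = 0.0,
    seed: int | None = None,
    dialect: str = "plp-link",
    structure_id: str | None = None,
) -> tuple[StructureModel, FixtureManifest]:
    """Build one idealized PLP active site at exactly the requested geometry.

    ``internal_deg`` is the torsion C3-C4-C4A-NZ; ``external_deg`` (GD and
    IAA only) is the torsion C3-C4-C4A-N(ligand). ``jitter`` adds Gaussian
    coordinate noise of that standard deviation (A) using ``seed``;
    ``jitter=0`` is fully deterministic.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if state in ("GD", "IAA") and external_deg is None:
        raise ValueError(f"state {state} requires an external dihedral angle")
    if state in ("NAT", "PSF") and external_deg is not None:
        raise ValueError(f"state {state} forbids an external dihedral angle")
    if state == "PSF" and not persulfide:
        raise ValueError("state PSF requires persulfide=True")
    if state == "NAT" and persulfide:
        raise ValueError("state NAT is incompatible with a persulfide (that is PSF)")
    if dialect not in ("plp-link", "llp"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")

    names = _LLP_NAMES if dialect == "llp" else _PLP_NAMES

    pos: dict[str, np.ndarray] = {}
    for nm in _RING_ORDER:
        th = np.radians(_RING_ANGLES[nm])
        pos[nm] = IDEAL["ring_bond"] * np.array([np.cos(th), np.sin(th), 0.0])

    def outward(ring_atom: str) -> np.ndarray:
        return _unit(pos[ring_atom])

    pos["C2A"] = pos["C2"] + IDEAL["c_c"] * outward("C2")
    pos["O3"] = pos["C3"] + IDEAL["c3_o3"] * outward("C3")
    pos["C4A"] = pos["C4"] + IDEAL["c4_c4a"] * outward("C4")
    pos["C5A"] = pos["C5"] + IDEAL["c5_c5a"] * outward("C5")
    pos["O4P"] = place_atom(pos["C4"], pos["C5"], pos["C5A"],
                            IDEAL["c5a_o4p"], IDEAL["sp3_angle"], 180.0)
    pos["P"] = place_atom(pos["C5"], pos["C5A"], pos["O4P"],
                          IDEAL["o4p_p"], IDEAL["sp3_angle"], 180.0)
    for nm, tor in (("O1P", 60.0), ("O2P", 180.0), ("O3P", 300.0)):
        pos[nm] = place_atom(pos["C5A"], pos["O4P"], pos["P"],
                             IDEAL["p_o"], IDEAL["sp3_angle"], tor)

    # Schiff-base lysine arm, placed at the exact requested internal torsion.
    gem = state == "GD"
    nz_bond = IDEAL["c4a_n_single"] if gem else IDEAL["c4a_n_double"]
    nz_angle = IDEAL["sp3_angle"] if gem else IDEAL["sp2_angle"]
    pos["NZ"] = place_atom(pos["C3"], pos["C4"], pos["C4A"], nz_bond, nz_angle, internal_deg)
    pos["CE"] = place_atom(pos["C4"], pos["C4A"], pos["NZ"], IDEAL["n_ce"], 120.0, 180.0)
    pos["CD"] = place_atom(pos["C4A"], pos["NZ"], pos["CE"], IDEAL["c_c"], 111.0, 180.0)
    pos["CG"] = place_atom(pos["NZ"], pos["CE"], pos["CD"], IDEAL["c_c"], 111.0, 180.0)

    # Ligand alanine: covalently bonded (GD) or merely proximal (IAA).
    has_ligand = state in ("GD", "IAA")
    if has_ligand:
        n_bond = IDEAL["c4a_n_single"] if state == "GD" else IDEAL["iaa_n_c4a"]
        pos["LIG_N"] = place_atom(pos["C3"], pos["C4"], pos["C4A"],
                                  n_bond, IDEAL["sp3_angle"], external_deg)
        pos["LIG_CA"] = place_atom(pos["C4"], pos["C4A"], pos["LIG_N"], 1.47, 115.0, 60.0)
        pos["LIG_CB"] = place_atom(pos["C4A"], pos["LIG_N"], pos["LIG_CA"], IDEAL["c_c"], 110.0, 180.0)
        pos["LIG_C"] = place_atom(pos["C4A"], pos["LIG_N"], pos["LIG_CA"], IDEAL["c_c"], 110.0, -60.0)
        pos["LIG_O"] = place_atom(pos["LIG_N"], pos["LIG_CA"], pos["LIG_C"], 1.23, 120.0, 0.0)

    # Catalytic cysteine at the substrate-channel mouth, ~5 A off C4A.
    sg_dir = _unit(np.array([0.3, -0.6, 1.0]))
    pos["SG"] = pos["C4A"] + 5.0 * sg_dir
    pos["CB"] = pos["SG"] + IDEAL["cb_sg"] * _unit(np.array([0.2, -1.0, 0.3]))
    pos["CA"] = pos["CB"] + IDEAL["c_c"] * _unit(np.array([-0.8, -0.5, 0.4]))
    pos["N"] = pos["CA"] + 1.46 * _unit(np.array([-0.2, -1.0, -0.3]))
    if persulfide:
        pos["SD"] = pos["SG"] + IDEAL["ss"] * _unit(np.array([0.1, 0.4, 1.0]))

    if jitter > 0:
        rng = np.random.default_rng(seed)
        for nm in pos:
            pos[nm] = pos[nm] + rng.normal(0.0, jitter, size=3)

    # --- assemble the model ------------------------------------------------
    if structure_id is None:
        structure_id = f"synthetic-{state.lower()}"
    model = StructureModel(id=structure_id)
    chain = Chain(id="A")
    serial = 0

    def add(res: Residue, name: str, element: str, key: str, het: bool) -> None:
        nonlocal serial
        serial += 1
        res.atoms.append(Atom(serial=serial, name=name, element=element, alt_loc="",
                              occupancy=1.0, b_factor=20.0, coords=pos[key].copy(), is_het=het))

    cys_atoms = [("N", "N"), ("CA", "C"), ("CB", "C"), ("SG", "S")]
    if persulfide:
        cys_atoms.append(("SD", "S"))

    if dialect == "llp":
        llp = Residue(name="LLP", seq=216)
        for key in _RING_ORDER:
            add(llp, key, key[0], key, het=True)
        for key in ("C2A", "O3", "C4A", "C5A", "O4P", "P", "O1P", "O2P", "O3P"):
            add(llp, names[key], names[key][0], key, het=True)
        for key in ("NZ", "CE", "CD", "CG"):
            add(llp, key, key[0], key, het=True)
        chain.residues.append(llp)
    else:
        lys = Residue(name="LYS", seq=216)
        for key in ("CG", "CD", "CE", "NZ"):
            add(lys, key, key[0], key, het=False)
        chain.residues.append(lys)

    cys = Residue(name="CYS", seq=356)
    for name, el in cys_atoms:
        add(cys, name, el, name, het=False)
    chain.residues.append(cys)

    if dialect != "llp":
        plp = Residue(name="PLP", seq=401)
        for key in _RING_ORDER:
            add(plp, key, key[0], key, het=True)
        for key in ("C2A", "O3", "C4A", "C5A", "O4P", "P", "O1P", "O2P", "O3P"):
            el = "P" if key == "P" else key[0] if key[0] in "CON" else "O"
            add(plp, names[key], el, key, het=True)
        chain.residues.append(plp)

    if has_ligand:
        ala = Residue(name="ALA", seq=402)
        for name, key in (("N", "LIG_N"), ("CA", "LIG_CA"), ("CB", "LIG_CB"),
                          ("C", "LIG_C"), ("O", "LIG_O")):
            el = name[0]
            add(ala, name, el, key, het=True)
        chain.residues.append(ala)

    model.chains.append(chain)

    # Covalent-attachment LINK records (plp-link dialect; the fused LLP
    # residue already implies the internal bond).
    if dialect != "llp":
        model.links.append(LinkRecord(
            atom_a=AtomRef("A", "PLP", 401, "", "C4A"),
            atom_b=AtomRef("A", "LYS", 216, "", "NZ"),
            distance=round(distance(pos["C4A"], pos["NZ"]), 2),
        ))
    if state == "GD":
        plp_res, plp_seq = ("LLP", 216) if dialect == "llp" else ("PLP", 401)
        model.links.append(LinkRecord(
            atom_a=AtomRef("A", plp_res, plp_seq, "", names["C4A"]),
            atom_b=AtomRef("A", "ALA", 402, "", "N"),
            distance=round(distance(pos["C4A"], pos["LIG_N"]), 2),
        ))

    d_nz_o3 = distance(pos["NZ"], pos["O3"])
    d_nlig_o3 = distance(pos["LIG_N"], pos["O3"]) if has_ligand else None
    d_nz_nlig = distance(pos["NZ"], pos["LIG_N"]) if has_ligand else None

    manifest = FixtureManifest(
        requested_internal_deg=float(internal_deg),
        requested_external_deg=None if external_deg is None else float(external_deg),
        state=state,
        persulfide=persulfide,
        dialect=dialect,
        jitter=float(jitter),
        atoms=[(chain.id, r.name, r.seq, a.name, tuple(map(float, a.coords)))
               for r in chain.residues for a in r.atoms],
        expected_state=state,
        expected_triangle=(d_nz_o3, d_nlig_o3, d_nz_nlig),
    )
    return model, manifest


_RADIUS_TO_ELEMENT = {1.70: "C", 1.55: "N", 1.52: "O", 1.80: "S"}


def make_two_sphere_fixture(radius: float, separation: float) -> StructureModel:
    """Two single-atom residues on separate chains, for SASA oracles.

    ``radius`` must correspond to an element in the default radius table
    (1.70 C, 1.55 N, 1.52 O, 1.80 S); the atoms are placed ``separation``
    apart along x.
    """
    if radius <= 0 or separation < 0:
        raise ValueError("radius must be > 0 and separation >= 0")
    element = None
    for r, el in _RADIUS_TO_ELEMENT.items():
        if abs(r - radius) < 1e-9:
            element = el
    if element is None:
        raise ValueError(f"radius {radius} has no element in the default table")
    model = StructureModel(id="two-sphere")
    for i, (cid, x) in enumerate((("A", 0.0), ("B", separation))):
        res = Residue(name="SPH", seq=1)
        res.atoms.append(Atom(serial=i + 1, name=element, element=element, alt_loc="",
                              occupancy=1.0, b_factor=0.0,
                              coords=np.array([x, 0.0, 0.0]), is_het=False))
        model.chains.append(Chain(id=cid, residues=[res]))
    return model


def make_dimer_fixture(n_atoms_per_chain: int, contact_fraction: float, seed: int) -> StructureModel:
    """Two compact seeded pseudo-chains meeting at a planar contact patch.

    ``contact_fraction`` in [0, 1] slides the chains together: 0 leaves a
    gap wide enough that no solvent-expanded spheres touch (zero burial),
    1 brings the flat faces into full contact. Same seed, same model.
    """
    if n_atoms_per_chain < 10:
        raise ValueError("need at least 10 atoms per chain")
    if not (0.0 <= contact_fraction <= 1.0):
        raise ValueError("contact_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_atoms_per_chain and attempts < 100000:
        attempts += 1
        cand = rng.uniform([-6.5, -4.5, -4.5], [0.0, 4.5, 4.5])
        if all(np.linalg.norm(cand - p) >= 2.2 for p in pts):
            pts.append(cand)
    if len(pts) < n_atoms_per_chain:
        raise RuntimeError("could not place atoms with the required separation")

    gap = 16.5 - 13.0 * contact_fraction  # face-to-face distance along x
    model = StructureModel(id=f"toy-dimer-f{contact_fraction:g}")
    for cid, sign, offset in (("A", 1.0, 0.0), ("B", -1.0, gap)):
        chain = Chain(id=cid)
        for i, p in enumerate(pts):
            res = Residue(name="DUM", seq=i + 1)
            x = offset + sign * p[0]
            res.atoms.append(Atom(serial=0, name="C", element="C", alt_loc="",
                                  occupancy=1.0, b_factor=0.0,
                                  coords=np.array([x, p[1], p[2]]), is_het=False))
            chain.residues.append(res)
        model.chains.append(chain)
    return model
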