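"""PLP active-site analysis: Schiff-base dihedrals, catalytic states, contacts.

The central quantities are the two signed dihedral angles of the Schiff-base
linkage relative to the PLP pyridine ring:

* **internal** dihedral — torsion over C3-C4-C4A-NZ, where NZ is the
  active-site lysine nitrogen of the internal aldimine;
* **external** dihedral — torsion over C3-C4-C4A-N(ligand), where the
  nitrogen is the amine of a bound (gem-diamine) or nearby (free amino
  acid) ligand.

With this atom ordering, internal aldimine angles come out positive and
external ones negative in the catalytically relevant conformations, and the
two angles share one consistent sign convention. The alternative
"plane-bond" convention (elevation of the C4A-N bond above the fitted ring
plane, signed by side) is available through :class:`~plpgeom.config.RunConfig`.

Catalytic states follow the desulfurase cycle: NAT (internal aldimine
only), GD (gem-diamine, C4A bonded to both nitrogens), IAA (internal
aldimine with a free amino-acid ligand in the site), PSF (internal aldimine
with a persulfide-modified catalytic cysteine). A persulfide co-occurring
with GD or IAA does not change those labels, since sulfur transfer precedes
ligand release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import mean, stdev

import numpy as np

from .config import RunConfig
from .geom import distance, fit_plane, torsion
from .structure_io import Atom, Chain, Residue, StructureModel

__all__ = [
    "PLPSite",
    "DihedralReport",
    "StateSummary",
    "MalformedCofactorError",
    "find_plp_sites",
    "internal_dihedral",
    "external_dihedral",
    "classify_state",
    "detect_persulfide",
    "hbond_contacts",
    "triangle_distances",
    "analyze_model",
    "summarize",
]

_COFACTOR_NAMES = {"PLP", "LLP"}
_RING_NAMES = ("N1", "C2", "C3", "C4", "C5", "C6")
_C4A_ALIASES = ("C4A", "C4'")
_O3_ALIASES = ("O3", "O3'")
_PHOSPHATE_ALIASES = {
    "P": ("P",),
    "O1P": ("O1P", "OP1"),
    "O2P": ("O2P", "OP2"),
    "O3P": ("O3P", "OP3"),
    "O4P": ("O4P", "OP4", "O5'"),
}
_CYS_NAMES = {"CYS", "CSS", "CSO", "CSD", "CME", "OCS"}

# Heavy-atom H-bond participants for the standard residues; het groups and
# waters contribute every N/O/S atom.
_BACKBONE_POLAR = {"N", "O", "OXT"}
_SIDECHAIN_POLAR = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"}, "MET": {"SD"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"OD1", "ND2"}, "GLN": {"OE1", "NE2"}, "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"}, "TRP": {"NE1"},
    "CSS": {"SG", "SD"}, "CSO": {"SG", "OD"},
}


class MalformedCofactorError(ValueError):
    """A PLP/LLP residue whose ring atoms cannot be resolved or validated."""


@dataclass
class PLPSite:
    """One PLP active site with the atoms the dihedral analysis needs."""

    chain_id: str
    residue: Residue
    ring_atoms: dict[str, Atom]
    c4a: Atom
    o3: Atom | None
    phosphate_atoms: dict[str, Atom]
    internal_partner: Atom | None
    internal_partner_label: str | None
    internal_covalent: bool
    external_ligand: Atom | None
    external_ligand_label: str | None
    external_covalent: bool
    catalytic_cys: Residue | None
    dialect: str  # "fused" (LLP-style) or "linked" (PLP + LINK/proximity)


@dataclass
class DihedralReport:
    """One per-protomer row: the unit of the rendered angle table."""

    structure: str
    protomer: str
    internal_deg: float | None
    external_deg: float | None
    state: str


@dataclass
class StateSummary:
    """Per-state mean and sample standard deviation of both dihedrals."""

    state: str
    mean_internal: float | None
    sd_internal: float | None
    mean_external: float | None
    sd_external: float | None
    n: int


def _atom_of(residue: Residue, *names: str) -> Atom | None:
    for n in names:
        a = residue.atom(n)
        if a is not None:
            return a
    return None


def _residue_label(chain: Chain, res: Residue) -> str:
    return f"{chain.id}/{res.name}{res.seq}{res.icode}"


def find_plp_sites(model: StructureModel, config: RunConfig | None = None) -> list[PLPSite]:
    """Locate every PLP/LLP cofactor and assemble its active-site context.

    Handles both deposition dialects: a fused lysine-PLP residue (LLP-style
    primed atom names, the lysine nitrogen inside the same residue) and a
    separate PLP het group whose Schiff-base partner is found as a lysine
    NZ within the covalent cutoff of C4A. Raises
    :class:`MalformedCofactorError` when a cofactor's six-membered ring
    cannot be resolved or its bond distances are not ring-like.
    """
    cfg = config or RunConfig()
    sites: list[PLPSite] = []
    for chain in model.chains:
        for res in chain.residues:
            if res.name.upper() not in _COFACTOR_NAMES:
                continue
            ring = {n: res.atom(n) for n in _RING_NAMES}
            missing = [n for n, a in ring.items() if a is None]
            if missing:
                raise MalformedCofactorError(
                    f"{_residue_label(chain, res)}: ring atoms missing: {missing}")
            cycle = [ring[n].coords for n in _RING_NAMES]
            for i in range(6):
                d = distance(cycle[i], cycle[(i + 1) % 6])
                if not (1.2 <= d <= 1.6):
                    raise MalformedCofactorError(
                        f"{_residue_label(chain, res)}: ring bond "
                        f"{_RING_NAMES[i]}-{_RING_NAMES[(i + 1) % 6]} = {d:.2f} A "
                        "outside 1.2-1.6 A")
            c4a = _atom_of(res, *_C4A_ALIASES)
            if c4a is None:
                raise MalformedCofactorError(
                    f"{_residue_label(chain, res)}: no Schiff-base carbon (C4A/C4')")
            o3 = _atom_of(res, *_O3_ALIASES)
            phosphate = {}
            for canon, aliases in _PHOSPHATE_ALIASES.items():
                a = _atom_of(res, *aliases)
                if a is not None:
                    phosphate[canon] = a

            # Internal Schiff-base partner: fused NZ, or a lysine NZ nearby.
            partner = res.atom("NZ")
            partner_label = _residue_label(chain, res) if partner is not None else None
            dialect = "fused" if partner is not None else "linked"
            if partner is None:
                best = None
                for c2 in model.chains:
                    for r2 in c2.residues:
                        if r2.name.upper() != "LYS":
                            continue
                        nz = r2.atom("NZ")
                        if nz is None:
                            continue
                        d = distance(nz.coords, c4a.coords)
                        if d <= cfg.covalent_cutoff and (best is None or d < best[0]):
                            best = (d, nz, _residue_label(c2, r2))
                if best is not None:
                    partner, partner_label = best[1], best[2]
            internal_covalent = partner is not None and (
                distance(partner.coords, c4a.coords) <= cfg.covalent_cutoff)

            # External ligand: amine nitrogen of a non-water het group.
            ligand = None
            ligand_label = None
            best_d = None
            for c2 in model.chains:
                for r2 in c2.residues:
                    if r2 is res or r2.is_water:
                        continue
                    if r2.name.upper() in _COFACTOR_NAMES:
                        continue
                    if not any(a.is_het for a in r2.atoms):
                        continue
                    n_atom = r2.atom("N") or r2.atom("N1")
                    if n_atom is None or n_atom.element != "N":
                        continue
                    d = distance(n_atom.coords, c4a.coords)
                    if d <= cfg.ligand_proximity_max and (best_d is None or d < best_d):
                        best_d, ligand, ligand_label = d, n_atom, _residue_label(c2, r2)
            external_covalent = ligand is not None and best_d <= cfg.covalent_cutoff

            # Catalytic cysteine: nearest SG to C4A within the search radius.
            cat_cys = None
            best_sg = None
            for r2 in chain.residues:
                if r2.name.upper() not in _CYS_NAMES:
                    continue
                sg = r2.atom("SG")
                if sg is None:
                    continue
                d = distance(sg.coords, c4a.coords)
                if d <= cfg.catalytic_cys_max and (best_sg is None or d < best_sg):
                    best_sg, cat_cys = d, r2

            sites.append(PLPSite(
                chain_id=chain.id,
                residue=res,
                ring_atoms=ring,
                c4a=c4a,
                o3=o3,
                phosphate_atoms=phosphate,
                internal_partner=partner,
                internal_partner_label=partner_label,
                internal_covalent=internal_covalent,
                external_ligand=ligand,
                external_ligand_label=ligand_label,
                external_covalent=external_covalent,
                catalytic_cys=cat_cys,
                dialect=dialect,
            ))
    return sites


def _ring_normal(site: PLPSite) -> np.ndarray:
    """Ring-plane normal oriented by the N1->C2->C3 atom order (right-handed)."""
    fitres = fit_plane([site.ring_atoms[n].coords for n in _RING_NAMES])
    n = fitres.unit_normal
    a, b, c = (site.ring_atoms[x].coords for x in ("N1", "C2", "C3"))
    hand = np.cross(b - a, c - b)
    if np.dot(hand, n) < 0:
        n = -n
    return n


def _dihedral_to(site: PLPSite, n_atom: Atom, convention: str) -> float:
    if convention == "plane-bond":
        u = n_atom.coords - site.c4a.coords
        u = u / np.linalg.norm(u)
        s = float(np.clip(np.dot(u, _ring_normal(site)), -1.0, 1.0))
        # negated so the elevation sign matches the torsion convention
        # (a positive C3-C4-C4A-N torsion puts N on the -normal side)
        return float(-np.degrees(np.arcsin(s)))
    return torsion(site.ring_atoms["C3"].coords, site.ring_atoms["C4"].coords,
                   site.c4a.coords, n_atom.coords)


def internal_dihedral(site: PLPSite, config: RunConfig | None = None) -> float | None:
    """Signed internal Schiff-base dihedral (degrees), or None if no partner."""
    cfg = config or RunConfig()
    if site.internal_partner is None:
        warnings.warn(f"site {site.chain_id}: no internal Schiff-base nitrogen", stacklevel=2)
        return None
    return _dihedral_to(site, site.internal_partner, cfg.convention)


def external_dihedral(site: PLPSite, config: RunConfig | None = None) -> float | None:
    """Signed external Schiff-base dihedral (degrees), or None without a ligand.

    For a covalently bonded ligand (gem-diamine) this is the external
    aldimine angle proper; for a merely proximal free amino acid it is the
    corresponding proposed angle toward the ligand amine.
    """
    cfg = config or RunConfig()
    if site.external_ligand is None:
        return None
    return _dihedral_to(site, site.external_ligand, cfg.convention)


def detect_persulfide(
    model: StructureModel, chain_id: str, config: RunConfig | None = None
) -> list[tuple[Residue, Atom]]:
    """Find persulfide-modified cysteines in a chain.

    A cysteine counts as persulfide-bound when an additional sulfur atom
    (from a het group or a modified residue) lies within the S-S bonding
    window of its SG.
    """
    cfg = config or RunConfig()
    chain = model.chain(chain_id)
    if chain is None:
        return []
    hits: list[tuple[Residue, Atom]] = []
    for res in chain.residues:
        if res.name.upper() not in _CYS_NAMES:
            continue
        sg = res.atom("SG")
        if sg is None:
            continue
        for _, r2, a2 in model.iter_atoms():
            if a2 is sg or a2.element != "S":
                continue
            if r2.name.upper() in _CYS_NAMES and a2.name == "SG" and r2 is not res:
                continue  # a disulfide partner is not a persulfide
            d = distance(a2.coords, sg.coords)
            if cfg.persulfide_min <= d <= cfg.persulfide_max:
                hits.append((res, a2))
    return hits


def classify_state(
    site: PLPSite, model: StructureModel, config: RunConfig | None = None
) -> str:
    """Assign the catalytic state of one active site.

    Decision rules, in order: GD when C4A is covalently bonded to both the
    lysine and the ligand nitrogens; IAA when the internal linkage is intact
    and a free amino-acid ligand sits within the proximity window; PSF when
    the internal linkage is intact, the catalytic cysteine carries a
    persulfide and no ligand is present; NAT when the internal linkage is
    intact with neither ligand nor persulfide; UNKNOWN otherwise. A
    persulfide seen alongside GD or IAA leaves those labels unchanged.
    """
    cfg = config or RunConfig()
    persulfides = detect_persulfide(model, site.chain_id, cfg)
    if site.catalytic_cys is not None:
        cys_persulfide = any(r is site.catalytic_cys for r, _ in persulfides)
    else:
        cys_persulfide = bool(persulfides)
    if site.external_covalent and site.internal_covalent:
        return "GD"
    if site.internal_covalent and site.external_ligand is not None and not site.external_covalent:
        return "IAA"
    if site.internal_covalent and site.external_ligand is None and cys_persulfide:
        return "PSF"
    if site.internal_covalent and site.external_ligand is None and not cys_persulfide:
        return "NAT"
    return "UNKNOWN"


def hbond_contacts(
    model: StructureModel,
    focus_atoms,
    cutoff: float | None = None,
    config: RunConfig | None = None,
) -> list[tuple[Atom, Atom, str, float]]:
    """Heavy-atom hydrogen-bond contacts of a set of focus atoms.

    Partners are N/O/S atoms from a fixed per-residue donor/acceptor table
    (every N/O/S atom for het groups and waters), within ``cutoff``
    (default 3.5 A), excluding atoms of the focus atoms' own residues. No
    angular criterion is applied because the inputs carry no hydrogens.
    Returns (focus atom, partner atom, partner residue label, distance)
    sorted by distance.
    """
    cfg = config or RunConfig()
    cut = cfg.hbond_cutoff if cutoff is None else cutoff
    if cut <= 0:
        raise ValueError("cutoff must be positive")
    focus = list(focus_atoms)
    if not focus:
        return []
    focus_ids = {id(a) for a in focus}
    # map atoms to their residues to exclude intra-residue pairs
    owner: dict[int, Residue] = {}
    for _, r, a in model.iter_atoms():
        owner[id(a)] = r
    out: list[tuple[Atom, Atom, str, float]] = []
    for f in focus:
        f_res = owner.get(id(f))
        for c2, r2, a2 in model.iter_atoms():
            if id(a2) in focus_ids or r2 is f_res:
                continue
            if a2.element not in ("N", "O", "S"):
                continue
            if not a2.is_het and not r2.is_water:
                polar = _BACKBONE_POLAR | _SIDECHAIN_POLAR.get(r2.name.upper(), set())
                if a2.name not in polar:
                    continue
            d = distance(f.coords, a2.coords)
            if d <= cut:
                out.append((f, a2, _residue_label(c2, r2), d))
    out.sort(key=lambda t: t[3])
    return out


def triangle_distances(
    site: PLPSite,
) -> tuple[float | None, float | None, float | None]:
    """Distances among the lysine NZ, ligand amine N, and ring hydroxyl O3.

    Returns (d(NZ, O3), d(Nlig, O3), d(NZ, Nlig)); entries are None where
    the corresponding atom is absent. In the gem-diamine both amino groups
    sit nearly equidistant from the hydroxyl, forming the near-equilateral
    proton-transfer triangle.
    """
    nz = site.internal_partner
    nlig = site.external_ligand
    o3 = site.o3
    d1 = distance(nz.coords, o3.coords) if nz is not None and o3 is not None else None
    d2 = distance(nlig.coords, o3.coords) if nlig is not None and o3 is not None else None
    d3 = distance(nz.coords, nlig.coords) if nz is not None and nlig is not None else None
    return (d1, d2, d3)


def analyze_model(model: StructureModel, config: RunConfig | None = None) -> list[DihedralReport]:
    """Full per-protomer analysis of one structure: one report row per site."""
    cfg = config or RunConfig()
    reports = []
    for site in find_plp_sites(model, cfg):
        reports.append(DihedralReport(
            structure=model.id,
            protomer=site.chain_id,
            internal_deg=internal_dihedral(site, cfg),
            external_deg=external_dihedral(site, cfg),
            state=classify_state(site, model, cfg),
        ))
    return reports


def _stats(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return (None, None)
    m = mean(values)
    s = stdev(values) if len(values) >= 2 else None
    return (m, s)


def summarize(reports: list[DihedralReport], pool_nat_psf: bool = True) -> list[StateSummary]:
    """Per-state means and sample standard deviations (n-1 denominator).

    NAT and PSF share the internal-aldimine geometry and are pooled into a
    joint "NAT and PSF" group (in addition to the unpooled groups) when
    ``pool_nat_psf`` is true. Full precision is retained; rendering rounds
    to one decimal.
    """
    if not reports:
        raise ValueError("summarize needs at least one report")
    groups: list[tuple[str, list[DihedralReport]]] = []
    if pool_nat_psf:
        pooled = [r for r in reports if r.state in ("NAT", "PSF")]
        if pooled:
            groups.append(("NAT and PSF", pooled))
    for state in ("NAT", "PSF", "GD", "IAA", "UNKNOWN"):
        members = [r for r in reports if r.state == state]
        if members:
            groups.append((state, members))
    out = []
    for label, members in groups:
        internal = [r.internal_deg for r in members if r.internal_deg is not None]
        external = [r.external_deg for r in members if r.external_deg is not None]
        mi, si = _stats(internal)
        me, se = _stats(external)
        out.append(StateSummary(state=label, mean_internal=mi, sd_internal=si,
                                mean_external=me, sd_external=se, n=len(members)))
    return out
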