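# Methods

## The geometric model

Cysteine desulfurases (CDS, EC 2.8.1.7) are PLP-dependent enzymes that move
sulfur from free L-cysteine onto a catalytic cysteine as a persulfide
(Cys-S-SH), releasing L-alanine. Catalysis proceeds through transaldimination:
the Schiff base between the cofactor's C4A and the active-site lysine NZ
(internal aldimine) exchanges with a Schiff base to the substrate amine
(external aldimine), passing through a tetrahedral gem-diamine in which C4A is
bonded to both nitrogens at once. The package quantifies the conformational
coordinate of this exchange: the rotation of the Schiff-base linkage relative
to the plane of the PLP pyridine ring.

Both angles are realized as one signed torsion over a fixed atom quadruple:

* internal dihedral = torsion(C3, C4, C4A, NZ)
* external dihedral = torsion(C3, C4, C4A, N_ligand)

with the IUPAC sign convention (positive = clockwise rotation of the fourth
atom relative to the first, looking down the C4→C4A axis). Sharing the
quadruple's first three atoms puts both angles in one frame, so internal
aldimine conformations come out positive and external/gem-diamine ligand
angles negative, matching how such tables are conventionally signed. An
alternative "plane-bond" convention — the elevation of the C4A–N bond above
the total-least-squares ring plane, signed by which side of the plane the
nitrogen occupies (negated so its sign agrees with the torsion convention) —
is available via `RunConfig(convention="plane-bond")` for cross-checking;
the torsion convention is the shipped default because it reproduces the
reference per-protomer values.

## Catalytic-state classification

States are a pure function of distances and connectivity:

| state | rule |
|---|---|
| GD | C4A covalently bonded (≤ 1.8 Å) to both NZ and the ligand amine |
| IAA | internal linkage intact, ligand amine within (1.8, 5.0] Å of C4A |
| PSF | internal linkage intact, persulfide on the catalytic Cys, no ligand |
| NAT | internal linkage intact, no ligand, no persulfide |
| UNKNOWN | anything else |

A persulfide seen together with GD or IAA does not change those labels —
sulfur transfer precedes ligand release, so gem-diamine and ligand-bound
sites routinely still carry the persulfide. Thresholds (covalent C4A–N
≤ 1.8 Å; persulfide S–S in 1.9–2.3 Å; ligand-proximity window (1.8, 5.0] Å;
catalytic-Cys search radius 12 Å from C4A) are standard covalent radii with
margin appropriate to 1.5–2.6 Å crystallographic coordinates; all are
exposed in `RunConfig`. The catalytic cysteine is the Cys whose SG lies
nearest C4A within the search radius (it sits at the substrate-channel
mouth), overridable by explicit residue number.

Hydrogen bonds use a heavy-atom distance criterion (≤ 3.5 Å default)
between N/O/S atoms drawn from a fixed per-residue donor/acceptor table
(every N/O/S atom for het groups and waters). No angular term is applied:
the input structures carry no hydrogens at these resolutions.

## Structure handling

Parsing (PDB and mmCIF, `LINK`/`struct_conn` connectivity) is delegated to
gemmi and rebuilt into a small chain/residue/atom model; writing is a
fixed-column PDB emitter owned by this package. Alternate locations are
collapsed on read — highest occupancy wins, ties broken by lexicographically
smallest altloc — so geometry always sees one conformer. Only the first
MODEL block is used. Residue numbering follows the author numbering in the
file. The Lys–PLP adduct is handled in both deposition dialects: a fused
LLP-style residue (primed atom names, NZ inside the residue) or a separate
PLP het group bonded to a lysine found by distance; `PLPSite.dialect`
records which was seen.

## Surface areas

SASA is Shrake–Rupley with a deterministic generalized golden-spiral point
set (default 960 points/atom), probe 1.4 Å, and element radii C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, other 1.80 Å. Per-atom area is the exposed
point fraction times the expanded-sphere area. Because the point set is
fixed in the laboratory frame, areas are exactly translation-invariant but
rotation-invariant only to the quadrature resolution (≲0.2% at 960 points
for molecule-sized inputs, shrinking with the point count); tests assert
translation invariance at 1e-9 and rotation invariance within that
quadrature window. Interface burial is reported per protomer — buried =
SASA(chain alone) − SASA(chain in the two-chain complex) — matching the
convention in which each protomer's buried area is quoted against its own
isolated accessible surface. Waters and hydrogens never contribute; het
groups are excluded from interface burial by default (`include_het=True`
to change), since the cofactor sits in the dimer interface and protomer
areas are conventionally protein-only. The exact SASA method and radii used
for the reference interface numbers are not published, so comparisons
against them carry a ±5% method window.

## Synthetic structures

`make_aldimine_model` builds one idealized active site per call: a planar
pyridine ring (1.39 Å bonds), the C3 hydroxyl, a five-atom phosphate arm,
and a lysine fragment whose NZ is placed by exact internal-coordinate
construction so the requested torsion is realized to machine precision;
GD/IAA add an alanine whose amine sits at the requested external torsion
(bonded at 1.47 Å for GD, free at 3.0 Å for IAA), PSF adds a persulfide
cysteine (S–S 2.05 Å). Bond lengths and angles are fixed chemically
plausible idealizations; they are deliberately not refined, because tests
compare pipeline output against the generator's manifest, not against
chemistry. Fixtures emulate connectivity and ideal geometry only — not
thermal disorder, alternate conformers, crystal contacts, solvent, or
refinement artifacts of real deposits — so passing round-trip tests
demonstrates correctness of the measurement machinery, not robustness to
everything real data can contain. The accession-based tests exist precisely
to close that gap when the deposited files are available locally.

Jitter is per-coordinate Gaussian noise of the given σ (Å) from a
caller-seeded generator; σ = 0 is byte-deterministic. Note the error
propagation: σ = 0.05 Å on all four quadrupole atoms with ~1.1–1.2 Å lever
arms yields ~5–6° rms torsion noise, so recovered angles at that noise
level scatter by several degrees by construction; the acceptance script
reports this rms honestly rather than hiding it.

`make_two_sphere_fixture` and `make_dimer_fixture` provide analytic SASA
oracle inputs: two equal spheres (spherical-cap closed form) and two
compact seeded pseudo-chains whose planar contact is slid from no-contact
(zero burial) to full contact by `contact_fraction`.

## Numerical choices

* Angles in degrees everywhere, range (−180°, 180°]; exact trans reports
  +180°. Collinear torsion input raises rather than returning a value.
* Plane fitting is total least squares via SVD; the normal's sign is fixed
  toward +z (ties: +x, then +y) so signed quantities are reproducible.
  Collinear input (second singular value ~0) raises.
* Kabsch superposition corrects reflections by the determinant sign of the
  SVD cross-covariance, guaranteeing a proper rotation.
* Reports round to one decimal in TSV; JSON keeps full precision. Means and
  sample standard deviations (n−1) are computed at full precision and
  rounded only on render; NAT and PSF are pooled in an additional summary
  row (both share the internal-aldimine geometry), with unpooled rows also
  emitted.
* All randomness (jitter, dimer fixtures) flows from caller-supplied seeds;
  there is no unseeded randomness anywhere, and identical inputs give
  byte-identical reports.

## Problem sizes

The shipped tests and the acceptance script run on the synthetic grid
(11 internal × {1, 1, 4, 4} state/external combinations = 110 models per
jitter level), 1000 random torsion quadruples, and two-sphere/30-atom-dimer
SASA fixtures at 960 and 4096 points — sizes chosen so the whole analysis
re-runs in seconds while still exercising every code path.

## Known limitations

* Rotation invariance of SASA is quadrature-limited (see above); use more
  points where sub-0.1% invariance matters.
* The H-bond criterion is distance-only; with hydrogens present a
  donor–H–acceptor angle term would be stricter.
* No protonation-state inference, no transaldimination energetics, no
  electron-density validation of ligands, and no symmetry-mate interface
  enumeration: the package measures deposited coordinates as given.
* The external-ligand detector keys on an amine nitrogen named N/N1 in a
  non-water het group within 5 Å of C4A; exotically named ligands need the
  explicit config hooks.
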