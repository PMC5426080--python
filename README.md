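# plpgeom

Active-site geometry of PLP-dependent enzymes, built around the catalytic
cycle of cysteine desulfurase (CDS, EC 2.8.1.7) — the enzyme that transfers
sulfur from free L-cysteine onto its catalytic cysteine as a persulfide and
releases L-alanine. It is written for structural biologists who have
crystal structures of such enzymes (PDB or mmCIF) and want reproducible
numbers for the questions those structures raise:

* Where are the pyridoxal 5′-phosphate (PLP) active sites, and is the
  cofactor deposited as a fused lysine adduct (LLP) or as PLP plus a LINK
  record?
* What are the signed **internal** and **external Schiff-base dihedral
  angles** — the torsions φ = C3–C4–C4A–N with N = Lys NZ (internal) or
  the ligand amine (external) — that track the transaldimination coordinate?
* Which catalytic intermediate does each protomer represent: native
  internal aldimine (**NAT**), gem-diamine (**GD**), internal aldimine with
  a free amino-acid ligand (**IAA**), or persulfide-bound (**PSF**)?
* Is the catalytic cysteine persulfide-modified, and what hydrogen-bond
  network holds the 5′-phosphate and the persulfide?
* How much surface does each protomer bury at the obligate dimer interface
  (Shrake–Rupley SASA, per-protomer burial)?

A synthetic-structure generator builds idealized active sites at exactly
requested geometry, so the entire pipeline is testable with no downloads.

## Worked example

Generate one idealized structure per catalytic state and analyze them:

```sh
plpgeom synth nat.pdb --state NAT --internal 47.7
plpgeom synth gd.pdb  --state GD  --internal 69.1 --external -50.2
plpgeom synth iaa.pdb --state IAA --internal 53.3 --external -51.4
plpgeom synth psf.pdb --state PSF --internal 38.3
plpgeom analyze nat.pdb gd.pdb iaa.pdb psf.pdb
```

prints

```
structure	protomer	internal_deg	external_deg	state
nat	A	47.7	n.a.	NAT
gd	A	69.1	-50.2	GD
iaa	A	53.3	-51.4	IAA
psf	A	38.3	n.a.	PSF

state	internal_mean	internal_sd	external_mean	external_sd	n
NAT and PSF	43.0	6.7	n.a.	n.a.	2
NAT	47.7	n.a.	n.a.	n.a.	1
PSF	38.3	n.a.	n.a.	n.a.	1
GD	69.1	n.a.	-50.2	n.a.	1
IAA	53.3	n.a.	-51.4	n.a.	1
```

Each row is one protomer: the internal dihedral (positive, internal
aldimine side), the external dihedral (negative, ligand side; `n.a.` when
no ligand is present), and the classified state. The summary block gives
per-state means and sample standard deviations, with NAT and PSF pooled
(both are internal-aldimine conformations) in addition to the unpooled
rows. The same numbers come out of the library:

```python
from plpgeom import read_structure, find_plp_sites, internal_dihedral, classify_state

model = read_structure("gd.pdb")
site = find_plp_sites(model)[0]
internal_dihedral(site)        # 69.1
classify_state(site, model)    # 'GD'
```

Other subcommands: `plpgeom interface FILE A B` (per-protomer buried
surface area), `plpgeom hbonds FILE --chain A --resseq 401` (heavy-atom
hydrogen-bond contacts), `plpgeom persulfide FILE` (persulfide-modified
cysteines). All thresholds, the SASA parameters, and the dihedral
convention are adjustable (`--covalent-cutoff`, `--probe`, `--n-points`,
`--convention {torsion,plane-bond}`, ...).

## Layout

```
src/plpgeom/
  structure_io.py   PDB/mmCIF reading (gemmi), fixed-column PDB writing, selection
  geom.py           torsions, plane fits, Kabsch superposition, distances
  sites.py          PLP site detection, dihedrals, states, persulfide, H-bonds
  sasa.py           Shrake-Rupley SASA and per-protomer interface burial
  synth.py          idealized active-site / sphere / dimer fixture generators
  config.py         thresholds, radii, conventions (RunConfig)
  report.py, cli.py rendering and the plpgeom command
docs/methods.md     model, conventions, parameter rationale, limitations
```
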