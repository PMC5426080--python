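"""Run-wide configuration: geometric thresholds, SASA parameters, output options.

Defaults encode the shipped analysis conventions:

* dihedral convention ``"torsion"`` — the signed torsion over the atom
  quadruple C3-C4-C4A-N (ring carbon, ring carbon bearing the exocyclic
  Schiff-base carbon, that carbon, linked nitrogen). The alternative
  ``"plane-bond"`` convention (angle of the C4A-N bond against the fitted
  pyridine-ring plane, signed by the side of the plane the nitrogen lies on)
  is available for cross-checking.
* covalent C4A-N threshold 1.8 A; persulfide S-S window 1.9-2.3 A; a free
  amino-acid ligand counts as "present but not bonded" between 1.8 and
  5.0 A of C4A. These are standard covalent radii with margin appropriate
  to 1.5-2.6 A crystallographic coordinates.
* hydrogen bonds: heavy-atom donor/acceptor distance <= 3.5 A, no angular
  term (the input structures carry no hydrogens).
* SASA: probe 1.4 A, 960 deterministic spiral points per atom, element
  radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80, otherwise 1.80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_RADIUS_OTHER = 1.80


@dataclass
class RunConfig:
    convention: str = "torsion"          # "torsion" | "plane-bond"
    covalent_cutoff: float = 1.8         # A, C4A-N Schiff-base bond
    persulfide_min: float = 1.9          # A, S-S lower bound
    persulfide_max: float = 2.3          # A, S-S upper bound
    ligand_proximity_max: float = 5.0    # A, free-ligand N to C4A
    catalytic_cys_max: float = 12.0      # A, SG to C4A search radius
    hbond_cutoff: float = 3.5            # A, heavy-atom donor/acceptor
    probe_radius: float = 1.4            # A, solvent probe
    n_points: int = 960                  # SASA quadrature points per atom
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    radius_other: float = DEFAULT_RADIUS_OTHER
    include_het: bool = False            # het groups in interface burial
    output_format: str = "tsv"           # "tsv" | "json"
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.convention not in ("torsion", "plane-bond"):
            raise ValueError(f"unknown dihedral convention {self.convention!r}")
        for name in ("covalent_cutoff", "persulfide_min", "persulfide_max",
                     "ligand_proximity_max", "catalytic_cys_max",
                     "hbond_cutoff", "probe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        if self.output_format not in ("tsv", "json"):
            raise ValueError(f"unknown output format {self.output_format!r}")

    def radius_of(self, element: str) -> float:
        return self.radii.get(element.capitalize(), self.radius_other)
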