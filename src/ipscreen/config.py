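"""Run configuration: detection thresholds and pattern constants.

All distances are in Angstrom, all angles in degrees.  The detection
defaults mirror the documented defaults of the reference profiler
(PLIP); the pattern constants are the published geometric constraints
of the ten brivudine-derived interaction patterns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass(frozen=True)
class DetectionConfig:
    """Geometric thresholds for noncovalent interaction detection.

    Distance thresholds are inclusive upper bounds; angular windows are
    closed intervals.
    """

    #: binding-site carving cutoff around the ligand
    binding_site_cutoff: float = 7.5
    #: maximum donor-acceptor heavy-atom distance for hydrogen bonds
    hbond_max_distance: float = 4.1
    #: minimum D-H...A angle when an explicit hydrogen is present
    hbond_min_angle: float = 100.0
    #: minimum neighbor-D...A surrogate angle when hydrogens are absent
    hbond_min_angle_noh: float = 90.0
    #: maximum carbon-carbon distance for hydrophobic contacts
    hydrophobic_max_distance: float = 4.0
    #: maximum ring centroid-centroid distance for pi-stacking
    pistack_max_distance: float = 5.5
    #: maximum lateral (in-plane) centroid offset for pi-stacking
    pistack_max_offset: float = 2.0
    #: maximum interplanar angle for a parallel (face-to-face) stack
    pistack_parallel_max_angle: float = 30.0
    #: interplanar angle window for a T-shaped (edge-to-face) stack
    pistack_tshaped_angle_range: tuple[float, float] = (60.0, 90.0)
    #: maximum halogen-acceptor distance for halogen bonds
    halogen_max_distance: float = 4.0
    #: C-X...A angle window center and half-width at the halogen
    halogen_donor_angle: float = 165.0
    halogen_donor_tolerance: float = 30.0
    #: Y-A...X angle window center and half-width at the acceptor
    halogen_acceptor_angle: float = 120.0
    halogen_acceptor_tolerance: float = 30.0
    #: whether fluorine may act as a halogen-bond donor (off by default;
    #: fluorine's sigma-hole is negligible)
    fluorine_donates: bool = False

    ring_planarity_tolerance: float = 0.15
    #: slack added to the sum of covalent radii when inferring bonds
    bond_slack: float = 0.45

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")


@dataclass(frozen=True)
class PatternConfig:
    """Numeric constants of the ten interaction patterns A-J.

    The distal bands are open intervals (strict inequalities): an anchor
    sitting exactly on a boundary does not qualify.  Distances ``x`` are
    measured from the ligand-side anchor atom to the base-ring centroid.
    """

    #: pattern G: angle between the two directed donor->acceptor vectors
    parallel_hbond_angle_center: float = 180.0
    parallel_hbond_tolerance: float = 18.0
    #: pattern H: hydrophobic ligand-atom distance band to the base ring
    distal_hydrophobic_band: tuple[float, float] = (4.0, 6.5)
    #: pattern I: hydrogen-bond ligand-anchor distance band
    distal_hbond_band: tuple[float, float] = (5.4, 6.1)
    #: pattern J: halogen-atom distance band
    distal_halogen_band: tuple[float, float] = (7.8, 9.2)

    def __post_init__(self) -> None:
        for name in ("distal_hydrophobic_band", "distal_hbond_band",
                     "distal_halogen_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have lower < upper: ({lo}, {hi})")
        if not 0.0 < self.parallel_hbond_tolerance < 90.0:
            raise ValueError("parallel_hbond_tolerance must lie in (0, 90)")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a screening run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    patterns: PatternConfig = field(default_factory=PatternConfig)
    #: minimum pattern count for a ligand to be reported as a hit
    hit_min_count: int = 6
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        det = d.get("detection", {})
        pat = d.get("patterns", {})
        for key in ("pistack_tshaped_angle_range",):
            if key in det:
                det[key] = tuple(det[key])
        for key in ("distal_hydrophobic_band", "distal_hbond_band",
                    "distal_halogen_band"):
            if key in pat:
                pat[key] = tuple(pat[key])
        return cls(
            detection=DetectionConfig(**det),
            patterns=PatternConfig(**pat),
            hit_min_count=int(d.get("hit_min_count", 6)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
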