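"""Run configuration with the analysis defaults baked in.

All cutoffs and thresholds used across the pipeline live here so that a run
is fully described by one serializable object: the 10 Å network trim, the
burial thresholds (-3.0 / +1.05 Å), the consensus clustering cutoffs (1.5 Å
for residue nodes, 2.0 Å for Na+) with minimum cluster size 5, the membrane
anchor residues (52, 163, 214 of the rhodopsin reference), and the DVP
log2-fold-change thresholds (0.5 for the pH 5.0 screen; at pH 7.0, 2.0 for
GPR4/GPR68 and 0.5 for GPR65).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    trim_cutoff: float = 10.0
    alpha_edge: float = 9.0
    burial_core_max: float = -3.0
    burial_exposed_min: float = 1.05
    cna_cutoff: float = 1.5
    ion_cutoff: float = 2.0
    min_cluster_size: int = 5
    plane_anchors: tuple[int, int, int] = (52, 163, 214)
    reference_structure_id: str = "1F88_A"
    dvp_threshold: float = 0.5
    dvp_ph7_thresholds: dict[str, float] = field(
        default_factory=lambda: {"GPR4": 2.0, "GPR65": 0.5, "GPR68": 2.0}
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("trim_cutoff", "alpha_edge", "cna_cutoff", "ion_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be at least 1")
        if self.burial_core_max >= self.burial_exposed_min:
            raise ValueError("burial thresholds out of order")
        self.plane_anchors = tuple(int(a) for a in self.plane_anchors)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["plane_anchors"] = list(self.plane_anchors)
        return d

    def digest(self) -> str:
        """Stable hash identifying this configuration."""
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
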