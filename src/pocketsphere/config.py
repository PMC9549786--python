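"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the method's printed operating point; each value can be
overridden from a JSON or ``key=value`` config file or per-call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    shell_radius: float = 12.0       # Å, sphere template shell
    interface_radius: float = 4.5    # Å, protein-ligand interface residues
    contact_cutoff: float = 4.5      # Å, predicted contact residues (N4)
    clash_cutoff: float = 1.0        # Å, steric clash residues (cl)
    region_radius: float = 16.0      # Å, query region reduction
    nc_min: int = 10                 # acceptance: conserved pairs
    gdc_min: float = 55.0            # acceptance: all-atom similarity
    n4_min: int = 1                  # acceptance: contact residues
    cl_max: int = 2                  # acceptance: clash residues
    high_nc_min: int = 25            # high-confidence tier
    high_gdc_min: float = 65.0
    high_cl_max: int = 1
    overlap_frac: float = 0.80       # cluster merge: contact-set overlap
    centroid_cutoff: float = 2.0     # Å, cluster merge: ligand centroids
    conserved_cutoff: float = 4.0    # Å, representative-point cutoff for Nc
    exclusive_gdc: float = 70.0      # pocket-clustering GDC threshold
    unit: str = "CA"                 # alignment representative point
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load overrides from JSON or ``key=value`` lines."""
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        cfg = cls()
        valid = {f.name: f.type for f in fields(cls)}
        for key, value in data.items():
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            setattr(cfg, key, type(current)(value))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
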