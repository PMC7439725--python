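"""Simulation configuration.

The configuration mirrors the design of the assayed library: orthologous
human/mouse TSS pairs in three biotypes, random inactive negative controls
carrying 3 barcodes each, high-activity positive-control tiles carrying 60
barcodes each, TSS tiles carrying 13 barcodes, and three replicates per
cellular environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

BIOTYPES = ("eRNA", "lncRNA", "mRNA")
ENVIRONMENTS = ("hESC", "mESC")
SPECIES = ("human", "mouse")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic MPRA study with known ground truth.

    Effect-size scales (``cis_effect_sd``, ``trans_effect_sd``,
    ``motif_effect_sd``) are log2 activity units.  ``dna_depth`` and
    ``rna_depth`` are expected total counts per sequencing sample;
    ``nb_dispersion`` is the negative-binomial dispersion (variance =
    mu + dispersion * mu^2).
    """

    n_pairs: int = 500
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: {"eRNA": 1 / 3, "lncRNA": 1 / 3, "mRNA": 1 / 3}
    )
    frac_conserved: float = 0.5
    n_negative_controls: int = 200
    n_positive_controls: int = 4
    barcodes_per_class: dict[str, int] = field(
        default_factory=lambda: {"TSS": 13, "negative": 3, "positive": 60}
    )
    n_replicates: int = 3
    dna_depth: float = 5e6
    rna_depth: float = 5e6
    nb_dispersion: float = 0.05
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 0.6
    frac_cis: float = 0.4
    frac_trans: float = 0.18
    frac_compensatory: float = 0.5
    n_motifs: int = 8
    motif_effect_sd: float = 0.5
    n_tads: int = 50
    enhancers_per_tad: int = 10
    redundancy_correlation: float = 0.8
    n_expression_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_conserved": self.frac_conserved,
            "frac_cis": self.frac_cis,
            "frac_trans": self.frac_trans,
            "frac_compensatory": self.frac_compensatory,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name, value in self.biotype_proportions.items():
            if name not in BIOTYPES:
                raise ConfigurationError(f"unknown biotype {name!r}")
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"biotype proportion for {name} out of [0, 1]")
        if abs(sum(self.biotype_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("biotype proportions must sum to 1")
        counts = {
            "n_pairs": self.n_pairs,
            "n_negative_controls": self.n_negative_controls,
            "n_positive_controls": self.n_positive_controls,
            "n_replicates": self.n_replicates,
            "n_motifs": self.n_motifs,
            "n_tads": self.n_tads,
            "enhancers_per_tad": self.enhancers_per_tad,
            "n_expression_samples": self.n_expression_samples,
        }
        for name, value in counts.items():
            if value < 0 or (name in ("n_pairs", "n_replicates") and value <= 0):
                raise ConfigurationError(f"{name} must be positive, got {value}")
        for name, value in self.barcodes_per_class.items():
            if value <= 0:
                raise ConfigurationError(f"barcodes_per_class[{name}] must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ConfigurationError("sequencing depths must be positive")
        if not 0.0 <= self.redundancy_correlation <= 1.0:
            raise ConfigurationError("redundancy_correlation must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    Unknown keys raise :class:`ConfigurationError` so typos do not silently
    fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
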