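"""Run configuration: every tunable threshold in one validated record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds with their defaults.

    evalue_max          hmmscan hit acceptance threshold.
    max_intervening     genes allowed between two role-bearing genes of one
                        locus (rank-distance predicate uses max_intervening+1).
    max_gap_bp          maximum intergenic gap (bp) within a locus.
    adjacency_rank      rank distance defining "directly adjacent" for CpoB.
    require_plug        TBDT role requires both barrel and plug hits.
    circular            close replicons into a circle for rank adjacency.
    motor_box_window    residues into domain II in which the motor box may begin.
    min_strand          minimum beta-strand run length for the motor box.
    min_coil_flank      coil residues required on each side of the strand.
    comp_ratio          dominance ratio r for composition classification.
    comp_floor          minimum percentage for a dominant class.
    ppii_cutoff         per-residue PPII propensity counted as PPII-forming.
    """

    evalue_max: float = 1e-5
    max_intervening: int = 3
    max_gap_bp: int = 5000
    adjacency_rank: int = 1
    require_plug: bool = True
    circular: bool = False
    motor_box_window: int = 75
    min_strand: int = 3
    min_coil_flank: int = 3
    comp_ratio: float = 2.0
    comp_floor: float = 10.0
    ppii_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.evalue_max > 0, "evalue_max must be > 0"),
            (self.max_intervening >= 0, "max_intervening must be >= 0"),
            (self.max_gap_bp > 0, "max_gap_bp must be > 0"),
            (self.adjacency_rank >= 0, "adjacency_rank must be >= 0"),
            (self.motor_box_window >= 1, "motor_box_window must be >= 1"),
            (self.min_strand >= 1, "min_strand must be >= 1"),
            (self.min_coil_flank >= 0, "min_coil_flank must be >= 0"),
            (self.comp_ratio >= 1, "comp_ratio must be >= 1"),
            (0 <= self.comp_floor <= 100, "comp_floor must be in [0, 100]"),
            (0 <= self.ppii_cutoff <= 1, "ppii_cutoff must be in [0, 1]"),
            (self.seed >= 0, "seed must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
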