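"""Pipeline configuration: one YAML file, validated on load."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class DetectConfig:
    min_orf_aa: int = 60
    min_ext: int = 40
    s_min: float = 0.5
    allow_extra_cysteines: bool = False
    framework_gaps: list = field(
        default_factory=lambda: [[5, 40], [5, 200], [0, 0], [3, 3], [6, 30]]
    )


@dataclass
class MineConfig:
    aa_seed_length: int = 4
    nt_seed_length: int = 21
    min_overlap: int = 25
    min_overlap_identity: float = 1.0
    max_rounds: int = 10


@dataclass
class ExpressionConfig:
    min_match: int = 32
    #: count archive size in spots (the half-spot/spot asymmetric
    #: convention) or in half spots
    denominator: str = "spots"


@dataclass
class TreeConfig:
    gap_open: float = 10.0
    gap_extend: float = 0.5
    replicates: int = 100
    max_gap_fraction: float | None = None
    max_row_gap_fraction: float | None = None
    tm_window: int = 19
    tm_hydropathy_min: float = 1.6


@dataclass
class SyntenyConfig:
    max_gap: int = 1_000_000


@dataclass
class SimulateConfig:
    n_clusters: int = 1
    cluster_composition: list = field(
        default_factory=lambda: ["gonadulin", "aIGF", "relaxin"]
    )
    intergenic_distances: list = field(default_factory=lambda: [15000, 30000])
    decoy_length: int = 100_000
    n_spots: int = 10_000
    read_length: int = 100
    paired: bool = False
    error_rate: float = 0.0


@dataclass
class Config:
    seed: int = 0
    detect: DetectConfig = field(default_factory=DetectConfig)
    mine: MineConfig = field(default_factory=MineConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    trees: TreeConfig = field(default_factory=TreeConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_GROUPS = {f.name: f for f in fields(Config) if f.name != "seed"}


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; unknown keys are rejected."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for group, values in data.items():
        if group == "seed":
            cfg.seed = int(values)
            continue
        if group not in _GROUPS:
            raise ValueError(f"{path}: unknown config group {group!r}")
        target = getattr(cfg, group)
        known = {f.name for f in fields(target)}
        for key, val in (values or {}).items():
            if key not in known:
                raise ValueError(f"{path}: unknown key {group}.{key}")
            setattr(target, key, val)
    _validate(cfg)
    return cfg


def _validate(cfg: Config) -> None:
    if cfg.expression.denominator not in ("spots", "half_spots"):
        raise ValueError("expression.denominator must be 'spots' or 'half_spots'")
    if not 0 < cfg.mine.min_overlap_identity <= 1:
        raise ValueError("mine.min_overlap_identity must be in (0, 1]")
    if cfg.detect.min_orf_aa < 1 or cfg.expression.min_match < 1:
        raise ValueError("lengths must be positive")
    if len(cfg.detect.framework_gaps) != 5:
        raise ValueError("detect.framework_gaps needs exactly 5 intervals")
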