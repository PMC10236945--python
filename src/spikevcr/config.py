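"""Pipeline configuration and the canonical frequency-band table.

Every numeric constant that drives the analysis (filter order, epoch
window, state windows, network-selection quotas, cluster-search
parameters) lives in :class:`PipelineConfig` so that a run is fully
described by one object, serialisable to YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "BandDefinition",
    "PipelineConfig",
    "default_bands",
    "BROADBAND",
]

#: Broadband reconstruction range (Hz) used for spike-amplitude ranking.
BROADBAND = (2.0, 55.0)

# (index, name, low Hz, high Hz) — theta, alpha, beta and nine gamma
# sub-bands.  Note the deliberate gaps at 55–65 and 115–125 Hz (power-line
# harmonics in the original recordings).
_BAND_TABLE = (
    (1, "theta", 4.0, 8.0),
    (2, "alpha", 8.0, 14.0),
    (3, "beta", 15.0, 30.0),
    (4, "gamma1", 30.0, 45.0),
    (5, "gamma2", 45.0, 55.0),
    (6, "gamma3", 65.0, 75.0),
    (7, "gamma4", 75.0, 85.0),
    (8, "gamma5", 85.0, 95.0),
    (9, "gamma6", 95.0, 105.0),
    (10, "gamma7", 105.0, 115.0),
    (11, "gamma8", 125.0, 135.0),
    (12, "gamma9", 135.0, 145.0),
)


@dataclass(frozen=True)
class BandDefinition:
    """One passband of the analysis filterbank."""

    index: int
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"band {self.index} ({self.name}): edges must increase, "
                f"got {self.low}–{self.high} Hz"
            )


def default_bands() -> tuple[BandDefinition, ...]:
    """The 12-band analysis table (Hz)."""
    return tuple(BandDefinition(i, n, lo, hi) for i, n, lo, hi in _BAND_TABLE)


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Defaults reproduce the published protocol; alternatives that the
    protocol leaves open are exposed as explicit switches
    (``filter_stage``, ``amplitude_mode``, ``rank_aggregate``,
    ``quota_base``, ``bulk_rule``, ``active_rule``).
    """

    # -- preprocessing -------------------------------------------------
    band_table: tuple[BandDefinition, ...] = field(default_factory=default_bands)
    filter_order: int = 1500            # FIR order; 1501 taps, applied two-pass
    pad_seconds: float = 2.0            # recording margin required around epochs
    epoch_window: tuple[float, float] = (-1.0, 1.0)   # s, half-open
    filter_stage: str = "continuous"    # 'continuous' | 'epoch'

    # -- brain-state windows ------------------------------------------
    state_centers: dict = field(
        default_factory=lambda: {"pre": -0.750, "spike": 0.0}
    )
    state_length: float = 0.100         # s

    # -- spike-associated network selection ---------------------------
    san_top_k: int = 1000               # rank cut for trial persistence
    san_persistence: float = 0.75       # fraction of trials a source must survive
    san_top_fraction: float = 0.05      # quota of best-ranked sources kept
    san_min_island: int = 5             # minimum spatial component size
    amplitude_mode: str = "onset"       # 'onset' | 'window' (max |x| in ±10 ms)
    rank_aggregate: str = "mean"        # 'mean' | 'median'
    quota_base: str = "total"           # 'total' | 'survivors'

    # -- virtual resection --------------------------------------------
    bulk_fraction: float = 0.10         # two-tailed near-zero quota
    bulk_rule: str = "per_tail"         # 'per_tail' | 'magnitude'

    # -- cluster search ------------------------------------------------
    cluster_min_sources: int = 15
    cluster_fallback_step: int = 5      # ladder 15 -> 10 -> 5
    cluster_min_bands: int = 4
    threshold_step: float = 0.01
    active_rule: str = "both"           # 'both' | 'either' state survival

    # -- evaluation ----------------------------------------------------
    inside_fraction: float = 0.5        # overlap needed for an 'in' verdict

    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("san_persistence", "san_top_fraction", "bulk_fraction",
                     "threshold_step", "inside_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if len(self.band_table) < 1:
            raise ValueError("band_table must contain at least one band")
        for b in self.band_table:
            if not b.low < b.high:
                raise ValueError(f"band {b.index}: edges must increase")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be increasing")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError("filter_order must be a positive even integer")
        if self.filter_stage not in ("continuous", "epoch"):
            raise ValueError("filter_stage must be 'continuous' or 'epoch'")
        if self.amplitude_mode not in ("onset", "window"):
            raise ValueError("amplitude_mode must be 'onset' or 'window'")
        if self.rank_aggregate not in ("mean", "median"):
            raise ValueError("rank_aggregate must be 'mean' or 'median'")
        if self.quota_base not in ("total", "survivors"):
            raise ValueError("quota_base must be 'total' or 'survivors'")
        if self.bulk_rule not in ("per_tail", "magnitude"):
            raise ValueError("bulk_rule must be 'per_tail' or 'magnitude'")
        if self.active_rule not in ("both", "either"):
            raise ValueError("active_rule must be 'both' or 'either'")
        if self.cluster_min_sources < 1 or self.cluster_min_bands < 1:
            raise ValueError("cluster sizes must be positive")
        for key in ("pre", "spike"):
            if key not in self.state_centers:
                raise ValueError(f"state_centers missing '{key}'")

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_table"] = [
            {"index": b.index, "name": b.name, "low": b.low, "high": b.high}
            for b in self.band_table
        ]
        d["epoch_window"] = list(self.epoch_window)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        data = dict(mapping)
        if "band_table" in data:
            data["band_table"] = tuple(
                BandDefinition(**b) if isinstance(b, Mapping) else b
                for b in data["band_table"]
            )
        if "epoch_window" in data:
            data["epoch_window"] = tuple(data["epoch_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML or JSON file (keys mirror field names)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_mapping(data)
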