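"""Domain containers and the on-disk patient-bundle format.

A :class:`PatientBundle` carries everything the pipeline needs for one
subject: the source grid, the continuous source-space recording, the
spike catalog, an optional resection mask and the outcome label.  The
on-disk format is a single HDF5 container with a format-version tag and
a JSON snapshot of the configuration used to create it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SourceGrid",
    "SpikeCatalog",
    "ResectionMask",
    "PatientBundle",
    "BundleSchemaError",
    "BundleVersionError",
    "save_bundle",
    "load_bundle",
]

FORMAT_VERSION = "1"

MODES = ("step1", "step2")
OUTCOMES = ("favourable", "unfavourable", "unknown")


class BundleSchemaError(ValueError):
    """A required field is missing or malformed in a bundle file."""


class BundleVersionError(ValueError):
    """The bundle file carries an unknown format-version tag."""


@dataclass
class SourceGrid:
    """Regular 3-D source lattice with a grey-matter validity mask.

    ``positions`` holds every lattice node (mm); ``valid_mask`` marks the
    nodes treated as sources.  All downstream indexing (recordings,
    resection masks, network selections) is into the *valid* sources, in
    the order induced by ``positions[valid_mask]``.
    """

    positions: np.ndarray          # (n_nodes, 3) mm
    spacing: float = 5.0           # mm
    valid_mask: np.ndarray = None  # (n_nodes,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_nodes, 3)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.positions), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (len(self.positions),):
            raise ValueError("valid_mask length must match positions")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_positions(self) -> np.ndarray:
        """Positions of valid sources, (n_valid, 3) mm."""
        return self.positions[self.valid_mask]

    def validate(self) -> None:
        if self.n_valid < 1:
            raise ValueError("grid must contain at least one valid source")
        origin = self.positions.min(axis=0)
        steps = (self.positions - origin) / self.spacing
        if not np.allclose(steps, np.round(steps), atol=1e-9):
            raise ValueError("positions are not on a regular lattice")
        pos = self.valid_positions
        if len(pos) > 1:
            d, _ = cKDTree(pos).query(pos, k=2)
            nn = d[:, 1]
            if not np.allclose(nn, self.spacing, atol=1e-9):
                raise ValueError(
                    "nearest-neighbour distances deviate from grid spacing"
                )

    def adjacency_pairs(self, member_indices: np.ndarray) -> np.ndarray:
        """26-neighbourhood pairs among the given valid-source indices.

        Two sources are adjacent iff their Euclidean distance is at most
        sqrt(3) * spacing (plus a small tolerance), i.e. they share a
        face, edge or corner on the lattice.
        """
        member_indices = np.asarray(member_indices, dtype=int)
        pos = self.valid_positions[member_indices]
        radius = np.sqrt(3.0) * self.spacing + 1e-6
        pairs = cKDTree(pos).query_pairs(r=radius, output_type="ndarray")
        return pairs  # local indices into member_indices


@dataclass
class SpikeCatalog:
    """Spike-onset sample indices into the continuous recording."""

    onsets: np.ndarray  # strictly increasing sample indices
    fs: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)

    @property
    def n_spikes(self) -> int:
        return len(self.onsets)

    def validate(self, n_samples: int, min_spikes_warning: int = 30) -> None:
        if self.n_spikes < 1:
            raise ValueError("spike catalog must contain at least one onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("spike onsets must be strictly increasing")
        margin = int(round(self.fs))  # 1 s epoch half-width
        if self.onsets[0] < margin or self.onsets[-1] + margin >= n_samples:
            raise ValueError(
                "every onset must admit a full [-1, 1) s epoch inside the recording"
            )
        if self.n_spikes < min_spikes_warning:
            warnings.warn(
                f"only {self.n_spikes} spikes available "
                f"(inclusion criterion is >= {min_spikes_warning}); "
                "connectivity estimates may be unstable",
                stacklevel=2,
            )


@dataclass
class ResectionMask:
    """Set of valid-source indices inside the resection cavity."""

    member_indices: np.ndarray

    def __post_init__(self) -> None:
        self.member_indices = np.unique(
            np.asarray(self.member_indices, dtype=np.int64)
        )

    def validate(self, n_valid: int) -> None:
        if len(self.member_indices) and (
            self.member_indices.min() < 0 or self.member_indices.max() >= n_valid
        ):
            raise ValueError("resection indices fall outside the valid sources")


@dataclass
class PatientBundle:
    """One subject: grid, recording, spikes, optional resection, outcome."""

    grid: SourceGrid
    recording: np.ndarray          # (n_valid, n_samples), arbitrary units
    spikes: SpikeCatalog
    resection: Optional[ResectionMask] = None
    mode: str = "step2"            # 'step1' | 'step2'
    outcome: str = "unknown"       # 'favourable' | 'unfavourable' | 'unknown'
    patient_id: str = "synthetic"
    config_snapshot: str = ""      # JSON text of the generating config

    def __post_init__(self) -> None:
        self.recording = np.asarray(self.recording)

    def validate(self) -> None:
        self.grid.validate()
        if self.recording.ndim != 2:
            raise ValueError("recording must be a (sources, time) array")
        if self.recording.shape[0] != self.grid.n_valid:
            raise ValueError(
                f"recording has {self.recording.shape[0]} rows but the grid "
                f"has {self.grid.n_valid} valid sources"
            )
        self.spikes.validate(self.recording.shape[1])
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.mode == "step1" and self.resection is None:
            raise ValueError("step1 mode requires a resection mask")
        if self.resection is not None:
            self.resection.validate(self.grid.n_valid)


def export_positions_tsv(grid: SourceGrid, path: str | Path) -> None:
    """Write valid-source coordinates as TSV (x, y, z in mm, one row each)."""
    np.savetxt(
        path,
        grid.valid_positions,
        delimiter="\t",
        header="x_mm\ty_mm\tz_mm",
        comments="",
        fmt="%.6f",
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _dset(group: h5py.Group, name: str, data) -> None:
    # track_times=False keeps files byte-identical across repeated saves
    group.create_dataset(name, data=data, track_times=False)


def save_bundle(bundle: PatientBundle, path: str | Path) -> None:
    """Write a validated bundle to an HDF5 container."""
    bundle.validate()
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["mode"] = bundle.mode
        f.attrs["outcome"] = bundle.outcome
        f.attrs["patient_id"] = bundle.patient_id
        f.attrs["config_snapshot"] = bundle.config_snapshot
        g = f.create_group("grid")
        _dset(g, "positions", bundle.grid.positions)
        _dset(g, "valid_mask", bundle.grid.valid_mask)
        g.attrs["spacing"] = float(bundle.grid.spacing)
        _dset(f, "recording", bundle.recording)
        s = f.create_group("spikes")
        _dset(s, "onsets", bundle.spikes.onsets)
        s.attrs["fs"] = float(bundle.spikes.fs)
        if bundle.resection is not None:
            r = f.create_group("resection")
            _dset(r, "member_indices", bundle.resection.member_indices)


def load_bundle(path: str | Path) -> PatientBundle:
    """Read and validate a bundle; unknown versions are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise BundleSchemaError("missing required field 'format_version'")
        if str(version) != FORMAT_VERSION:
            raise BundleVersionError(
                f"unknown bundle format version {version!r} "
                f"(expected {FORMAT_VERSION!r})"
            )
        for required in ("grid", "recording", "spikes"):
            if required not in f:
                raise BundleSchemaError(f"missing required field '{required}'")
        g = f["grid"]
        for required in ("positions", "valid_mask"):
            if required not in g:
                raise BundleSchemaError(f"missing required field 'grid/{required}'")
        grid = SourceGrid(
            positions=g["positions"][()],
            spacing=float(g.attrs["spacing"]),
            valid_mask=g["valid_mask"][()],
        )
        s = f["spikes"]
        if "onsets" not in s:
            raise BundleSchemaError("missing required field 'spikes/onsets'")
        spikes = SpikeCatalog(onsets=s["onsets"][()], fs=float(s.attrs["fs"]))
        resection = None
        if "resection" in f:
            resection = ResectionMask(f["resection"]["member_indices"][()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # spike-count warning re-raised on use
            bundle = PatientBundle(
                grid=grid,
                recording=f["recording"][()],
                spikes=spikes,
                resection=resection,
                mode=str(f.attrs["mode"]),
                outcome=str(f.attrs["outcome"]),
                patient_id=str(f.attrs["patient_id"]),
                config_snapshot=str(f.attrs["config_snapshot"]),
            )
            bundle.validate()
    return bundle
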