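"""Spike-associated network (SAN) construction.

Five-step selection of the sources most consistently tied to spike
onsets: broadband amplitude ranking per trial, trial-persistence
filtering, a best-mean-rank quota, an optional union with the resection
cavity (step1 designs only), and pruning of small spatial islands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bundle import ResectionMask, SourceGrid
from .preprocess import BandEpochs

__all__ = [
    "RankMatrix",
    "SANSelection",
    "rank_sources",
    "rank_from_amplitude",
    "persistent_sources",
    "top_fraction",
    "assemble_san",
    "prune_islands",
    "connected_components",
]

RANK_SELECTED = "rank-selected"
RESECTION_FORCED = "resection-forced"


@dataclass
class RankMatrix:
    """Per-trial amplitude ranks (1 = largest |amplitude|), (trials, sources)."""

    ranks: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_sources(self) -> int:
        return self.ranks.shape[1]


@dataclass
class SANSelection:
    """Ordered SAN membership with per-member provenance."""

    member_indices: np.ndarray                  # sorted valid-source indices
    provenance: dict = field(default_factory=dict)  # index -> provenance flag
    step_counts: dict = field(default_factory=dict)  # step name -> survivor count

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


def rank_from_amplitude(amplitude: np.ndarray) -> RankMatrix:
    """Rank sources within each trial by |amplitude|, descending.

    Ties are broken by ascending source index (stable sort on the
    negated magnitudes), so ranking is fully deterministic.
    """
    amp = np.abs(np.asarray(amplitude, dtype=float))
    order = np.argsort(-amp, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n_trials, n_sources = amp.shape
    rows = np.arange(n_trials)[:, None]
    ranks[rows, order] = np.arange(1, n_sources + 1)[None, :]
    return RankMatrix(ranks=ranks)


def rank_sources(
    broadband_epochs: BandEpochs,
    onset_index: int | None = None,
    amplitude_mode: str = "onset",
    fs: float | None = None,
) -> RankMatrix:
    """Rank sources per trial by broadband amplitude at the spike onset.

    ``amplitude_mode='onset'`` uses |value| at the single onset sample;
    ``'window'`` uses the maximum |value| within ±10 ms of it.
    """
    x = broadband_epochs.values
    if onset_index is None:
        onset_index = broadband_epochs.onset_index
    if not 0 <= onset_index < x.shape[-1]:
        raise ValueError("onset index lies outside the epoch")
    if amplitude_mode == "onset":
        amp = np.abs(x[..., onset_index])
    elif amplitude_mode == "window":
        fs = fs or broadband_epochs.fs
        half = int(round(0.010 * fs))
        a = max(0, onset_index - half)
        b = min(x.shape[-1], onset_index + half + 1)
        amp = np.abs(x[..., a:b]).max(axis=-1)
    else:
        raise ValueError("amplitude_mode must be 'onset' or 'window'")
    return rank_from_amplitude(amp)


def persistent_sources(
    ranks: RankMatrix, top_k: int = 1000, persistence: float = 0.75
) -> np.ndarray:
    """Sources ranked within the first ``top_k`` in enough trials.

    A source survives if its rank is <= ``top_k`` in at least
    ``ceil(persistence * n_trials)`` trials.
    """
    if top_k > ranks.n_sources:
        top_k = ranks.n_sources
    need = int(np.ceil(persistence * ranks.n_trials))
    counts = (ranks.ranks <= top_k).sum(axis=0)
    return np.flatnonzero(counts >= need)


def top_fraction(
    survivors: np.ndarray,
    ranks: RankMatrix,
    fraction: float = 0.05,
    quota_base: str = "total",
    rank_aggregate: str = "mean",
) -> np.ndarray:
    """Best-ranked quota of the persistence survivors.

    Survivors are scored by their mean (or median) rank across trials,
    ascending; the best ``ceil(fraction * base)`` are kept, where the
    base is the total candidate-source count by default.  The quota is
    capped at the survivor count.
    """
    survivors = np.asarray(survivors, dtype=int)
    if len(survivors) == 0:
        raise ValueError(
            "no persistence survivors; loosen san_top_k or san_persistence"
        )
    base = ranks.n_sources if quota_base == "total" else len(survivors)
    quota = min(int(np.ceil(fraction * base)), len(survivors))
    sub = ranks.ranks[:, survivors].astype(float)
    if rank_aggregate == "mean":
        scores = sub.mean(axis=0)
    elif rank_aggregate == "median":
        scores = np.median(sub, axis=0)
    else:
        raise ValueError("rank_aggregate must be 'mean' or 'median'")
    order = np.lexsort((survivors, scores))  # score asc, index asc on ties
    return np.sort(survivors[order[:quota]])


def assemble_san(
    rank_selected: np.ndarray,
    resection: ResectionMask | None,
    mode: str = "step2",
) -> SANSelection:
    """Union of rank-selected sources with the resection cavity (step1).

    In step2 mode a supplied resection mask is ignored entirely — the
    selection stays blind to the surgical information.
    """
    rank_selected = np.asarray(rank_selected, dtype=int)
    provenance = {int(i): RANK_SELECTED for i in rank_selected}
    if mode == "step1":
        if resection is None:
            raise ValueError("step1 mode requires a resection mask")
        for i in resection.member_indices:
            provenance.setdefault(int(i), RESECTION_FORCED)
    elif mode != "step2":
        raise ValueError("mode must be 'step1' or 'step2'")
    members = np.array(sorted(provenance), dtype=int)
    return SANSelection(member_indices=members, provenance=provenance)


def connected_components(
    member_indices: np.ndarray, grid: SourceGrid
) -> list[np.ndarray]:
    """Connected components of the member set under 26-neighbour adjacency."""
    member_indices = np.asarray(member_indices, dtype=int)
    n = len(member_indices)
    if n == 0:
        return []
    pairs = grid.adjacency_pairs(member_indices)
    # union-find over local indices
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    return [member_indices[roots == r] for r in np.unique(roots)]


def prune_islands(
    san: SANSelection, grid: SourceGrid, min_island: int = 5
) -> SANSelection:
    """Drop spatial components with fewer than ``min_island`` members."""
    if min_island < 1:
        raise ValueError("min_island must be at least 1")
    keep: list[np.ndarray] = [
        comp
        for comp in connected_components(san.member_indices, grid)
        if len(comp) >= min_island
    ]
    if not keep:
        raise ValueError(
            "no spatial component reaches the minimum island size; "
            "the selection is empty after pruning"
        )
    members = np.sort(np.concatenate(keep))
    provenance = {int(i): san.provenance.get(int(i), RANK_SELECTED) for i in members}
    counts = dict(san.step_counts)
    counts["prune_islands"] = len(members)
    return SANSelection(
        member_indices=members, provenance=provenance, step_counts=counts
    )


def sanity_check_size(
    san: SANSelection, expected: tuple[int, int] = (500, 600)
) -> None:
    """Warn (never fail) when the SAN size leaves the cohort-scale band."""
    lo, hi = expected
    if not lo <= san.n_members <= hi:
        warnings.warn(
            f"SAN contains {san.n_members} sources, outside the typical "
            f"{lo}-{hi} band for full-scale recordings",
            stacklevel=2,
        )
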