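"""Spatio-spectral cluster search over control-centrality itineraries.

Each source carries, per frequency band, an itinerary: its role label in
the pre-spike state followed by its role at spike onset (D =
desynchronizing, S = synchronizing, B = bulk; nine combinations).  A
sequential thresholding sweep admits sources from the largest |CC|
magnitudes downwards (two-tailed, 1% steps) and, at every step, looks
for connected clusters of admitted cells that share one itinerary —
connectivity being 26-neighbour spatial adjacency within a band plus
same-source adjacency across consecutive band indices.  A cluster is
valid once at least ``min_sources`` sources hold the itinerary over at
least ``min_bands`` consecutive bands; the first cluster to emerge is
the candidate.  If the full sweep yields nothing, the minimum size is
lowered by five and the sweep restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .resection import CCStack

__all__ = [
    "Itinerary",
    "Cluster",
    "ClusterCandidate",
    "SearchResult",
    "itinerary_name",
    "itineraries",
    "threshold_active",
    "find_clusters",
    "sequential_search",
]

_ROLE_CHAR = {1: "D", -1: "S", 0: "B"}


@dataclass(frozen=True)
class Itinerary:
    """Ordered pair of roles: pre-spike label then spike-onset label."""

    pre: int    # +1 desynchronizing, -1 synchronizing, 0 bulk
    spike: int

    @property
    def name(self) -> str:
        return f"{_ROLE_CHAR[self.pre]}->{_ROLE_CHAR[self.spike]}"

    @property
    def code(self) -> int:
        return (self.pre + 1) * 3 + (self.spike + 1)


def itinerary_name(code: int) -> str:
    pre, spike = divmod(int(code), 3)
    return f"{_ROLE_CHAR[pre - 1]}->{_ROLE_CHAR[spike - 1]}"


def itineraries(cc_stack: CCStack) -> np.ndarray:
    """Itinerary code per (source, band), shape (n_sources, n_bands).

    Codes encode (pre_label, spike_label) pairs; decode with
    :func:`itinerary_name`.
    """
    pre = cc_stack.labels[:, cc_stack.states.index("pre"), :].astype(int)
    spike = cc_stack.labels[:, cc_stack.states.index("spike"), :].astype(int)
    return ((pre + 1) * 3 + (spike + 1)).T  # -> (sources, bands)


def threshold_active(
    cc_stack: CCStack, t: float, active_rule: str = "both"
) -> np.ndarray:
    """Boolean (source, band) activity at admission fraction ``t``.

    Per (band, state), a source is retained iff its |CC| lies within the
    top ``ceil(t * n)`` magnitudes (ties at the cut all included); a
    cell is active iff retained in both states (default) or either.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold fraction must lie in (0, 1]")
    mags = np.abs(cc_stack.cc)                      # (bands, 2, n)
    n = mags.shape[-1]
    k = int(np.ceil(t * n))
    cutoff = -np.sort(-mags, axis=-1)[..., k - 1]   # k-th largest per (band, state)
    retained = mags >= cutoff[..., None]
    if active_rule == "both":
        active = retained.all(axis=1)
    elif active_rule == "either":
        active = retained.any(axis=1)
    else:
        raise ValueError("active_rule must be 'both' or 'either'")
    return active.T                                  # -> (sources, bands)


@dataclass
class Cluster:
    """One valid spatio-spectral cluster (node indices are stack-local)."""

    sources: np.ndarray          # node indices, sorted
    band_run: tuple[int, int]    # inclusive run of band positions (0-based)
    itinerary_code: int
    mean_abs_cc: np.ndarray      # per source, over run bands and both states

    @property
    def size(self) -> int:
        return len(self.sources)

    @property
    def itinerary(self) -> str:
        return itinerary_name(self.itinerary_code)


@dataclass
class ClusterCandidate:
    """The first-emerging cluster of the sequential search."""

    sources: np.ndarray          # node indices into the CC stack
    band_interval: tuple[int, int]   # inclusive, in band-table indices (1..12)
    itinerary: str
    threshold: float             # emergence threshold, in (0, 1]
    min_size_level: int          # 15, 10 or 5
    mean_abs_cc: np.ndarray      # per member source
    source_ids: np.ndarray | None = None  # valid-source indices, if known

    @property
    def size(self) -> int:
        return len(self.sources)


@dataclass
class SearchResult:
    """Outcome of the sweep: a candidate or a typed no-solution."""

    candidate: ClusterCandidate | None
    trace: list = field(default_factory=list)  # (min_size, threshold, n_clusters)
    min_sizes_tried: tuple[int, ...] = ()

    @property
    def found(self) -> bool:
        return self.candidate is not None


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_clusters(
    active: np.ndarray,
    itins: np.ndarray,
    adjacency_pairs: np.ndarray,
    cc_stack: CCStack,
    min_sources: int = 15,
    min_bands: int = 4,
) -> list[Cluster]:
    """Connected same-itinerary components of active (source, band) cells.

    ``active`` and ``itins`` are (n_sources, n_bands); ``adjacency_pairs``
    lists spatially adjacent source pairs (stack-local indices).  A
    component yields a cluster when some run of >= ``min_bands``
    consecutive bands is shared by >= ``min_sources`` of its sources;
    among qualifying runs the longest wins (ties: more sources, then the
    lower starting band).
    """
    n_src, n_bands = active.shape
    uf = _UnionFind(n_src * n_bands)

    def cell(src: int, band: int) -> int:
        return src * n_bands + band

    # spatial adjacency within each band
    for a, b in adjacency_pairs:
        a, b = int(a), int(b)
        for band in range(n_bands):
            if (
                active[a, band]
                and active[b, band]
                and itins[a, band] == itins[b, band]
            ):
                uf.union(cell(a, band), cell(b, band))
    # same-source adjacency across consecutive bands
    for src in range(n_src):
        for band in range(n_bands - 1):
            if (
                active[src, band]
                and active[src, band + 1]
                and itins[src, band] == itins[src, band + 1]
            ):
                uf.union(cell(src, band), cell(src, band + 1))

    groups: dict[int, list[tuple[int, int]]] = {}
    for src in range(n_src):
        for band in range(n_bands):
            if active[src, band]:
                groups.setdefault(uf.find(cell(src, band)), []).append((src, band))

    mags = np.abs(cc_stack.cc)  # (bands, 2, n)
    clusters: list[Cluster] = []
    for cells in groups.values():
        srcs = sorted({c[0] for c in cells})
        present = np.zeros((len(srcs), n_bands), dtype=bool)
        local = {s: i for i, s in enumerate(srcs)}
        for src, band in cells:
            present[local[src], band] = True
        best = None  # (run_len, n_members, -b0, b0, b1, members)
        for b0 in range(n_bands):
            for b1 in range(b0 + min_bands - 1, n_bands):
                members = np.flatnonzero(present[:, b0 : b1 + 1].all(axis=1))
                if len(members) < min_sources:
                    continue
                key = (b1 - b0 + 1, len(members), -b0)
                if best is None or key > best[0]:
                    best = (key, b0, b1, members)
        if best is None:
            continue
        _, b0, b1, members = best
        member_srcs = np.array([srcs[m] for m in members], dtype=int)
        # mean |CC| over the run bands and both states, per member source
        m = mags[b0 : b1 + 1, :, :][:, :, member_srcs].mean(axis=(0, 1))
        clusters.append(
            Cluster(
                sources=member_srcs,
                band_run=(b0, b1),
                itinerary_code=int(itins[member_srcs[0], b0]),
                mean_abs_cc=m,
            )
        )
    return clusters


def _select(clusters: list[Cluster]) -> Cluster:
    """Most locked sources; tie -> larger mean |CC|; tie -> lower first band."""
    return max(
        clusters,
        key=lambda c: (c.size, float(c.mean_abs_cc.mean()), -c.band_run[0]),
    )


def sequential_search(
    cc_stack: CCStack,
    adjacency_pairs: np.ndarray,
    config: PipelineConfig | None = None,
) -> SearchResult:
    """1–100% admission sweep with the 15 -> 10 -> 5 minimum-size ladder."""
    config = config or PipelineConfig()
    itins = itineraries(cc_stack)
    step = config.threshold_step
    n_steps = int(round(1.0 / step))
    thresholds = [round((i + 1) * step, 10) for i in range(n_steps)]
    min_sizes = tuple(
        range(config.cluster_min_sources, 0, -config.cluster_fallback_step)
    )
    trace: list[tuple[int, float, int]] = []
    for min_size in min_sizes:
        for t in thresholds:
            active = threshold_active(cc_stack, t, config.active_rule)
            clusters = find_clusters(
                active,
                itins,
                adjacency_pairs,
                cc_stack,
                min_sources=min_size,
                min_bands=config.cluster_min_bands,
            )
            trace.append((min_size, t, len(clusters)))
            if clusters:
                chosen = _select(clusters)
                b0, b1 = chosen.band_run
                band_ids = cc_stack.band_indices
                candidate = ClusterCandidate(
                    sources=chosen.sources,
                    band_interval=(band_ids[b0], band_ids[b1]),
                    itinerary=chosen.itinerary,
                    threshold=t,
                    min_size_level=min_size,
                    mean_abs_cc=chosen.mean_abs_cc,
                    source_ids=(
                        None
                        if cc_stack.node_indices is None
                        else np.asarray(cc_stack.node_indices)[chosen.sources]
                    ),
                )
                return SearchResult(
                    candidate=candidate, trace=trace, min_sizes_tried=min_sizes
                )
    return SearchResult(candidate=None, trace=trace, min_sizes_tried=min_sizes)
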