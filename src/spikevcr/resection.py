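"""Virtual cortical resection: synchronizability and control centrality.

Synchronizability S of a weighted graph is the Laplacian eigenratio
lambda_2 / lambda_max (master-stability convention): larger S means the
network synchronizes more readily, and S = 0 iff the graph is
disconnected.  Control centrality of node i is the fractional change of
S under virtual deletion of that node,

    CC_i = (S_i - S) / S,

so CC_i > 0 marks a desynchronizing node (its removal makes the network
easier to synchronize) and CC_i < 0 a synchronizing one.  Sources whose
CC sits in the two-tailed fraction nearest zero are labelled bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components as _graph_components

from .connectivity import ConnectivityStack

__all__ = [
    "CCStack",
    "synchronizability",
    "control_centrality",
    "label_roles",
    "vcr_all",
]

_ZERO_TOL = 1e-12

#: role label encoding: +1 desynchronizing (CC > 0), -1 synchronizing, 0 bulk
DESYNCHRONIZING, SYNCHRONIZING, BULK = 1, -1, 0


@dataclass
class CCStack:
    """Synchronizability, control centrality and roles per (band, state).

    ``cc`` has shape (n_bands, 2, n); ``labels`` uses +1 for
    desynchronizing, -1 for synchronizing and 0 for bulk sources.
    """

    s: np.ndarray          # (n_bands, 2)
    cc: np.ndarray         # (n_bands, 2, n)
    labels: np.ndarray     # (n_bands, 2, n), int8
    band_indices: tuple[int, ...]
    states: tuple[str, str] = ("pre", "spike")
    node_indices: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.cc.shape[-1]


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if a.shape[0] < 2:
        raise ValueError("at least two nodes are required")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency weights must be nonnegative")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    return a


def synchronizability(adjacency: np.ndarray) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max, in [0, 1]."""
    a = _check_adjacency(adjacency)
    lap = np.diag(a.sum(axis=1)) - a
    eig = np.linalg.eigvalsh(lap)
    lam_max = eig[-1]
    if lam_max <= _ZERO_TOL:
        return 0.0  # empty graph
    lam2 = eig[1]
    if lam2 < _ZERO_TOL * max(1.0, lam_max):
        return 0.0  # disconnected
    return float(lam2 / lam_max)


def control_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Leave-one-node-out fractional change of synchronizability.

    Requires a connected graph (S > 0) of at least three nodes; deleting
    node i removes its row and column before S is recomputed.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    if n < 3:
        raise ValueError("control centrality needs at least three nodes")
    s = synchronizability(a)
    if s <= 0.0:
        raise ValueError(
            "control centrality is undefined on a disconnected graph (S = 0)"
        )
    cc = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        sub = a[np.ix_(keep, keep)]
        cc[i] = (synchronizability(sub) - s) / s
        keep[i] = True
    return cc


def label_roles(cc: np.ndarray, bulk_fraction: float = 0.10,
                bulk_rule: str = "per_tail") -> np.ndarray:
    """Triphasic role labels from a control-centrality vector.

    Exact zeros are bulk.  Under the default per-tail rule each sign
    tail contributes its ``ceil(bulk_fraction / 2 * n)`` values of
    smallest magnitude to the bulk (quota capped by tail occupancy, an
    unfilled quota is not reassigned).  The alternative magnitude rule
    takes the ``ceil(bulk_fraction * n)`` smallest |CC| regardless of
    sign.  Remaining positive values are desynchronizing (+1), negative
    synchronizing (-1).
    """
    cc = np.asarray(cc, dtype=float)
    if not np.all(np.isfinite(cc)):
        raise ValueError("control-centrality values must be finite")
    n = len(cc)
    labels = np.where(cc > 0, DESYNCHRONIZING, SYNCHRONIZING).astype(np.int8)
    labels[cc == 0] = BULK
    if bulk_rule == "per_tail":
        quota = int(np.ceil(bulk_fraction / 2.0 * n))
        for sign in (1, -1):
            tail = np.flatnonzero(np.sign(cc) == sign)
            order = tail[np.lexsort((tail, np.abs(cc[tail])))]
            labels[order[:quota]] = BULK
    elif bulk_rule == "magnitude":
        quota = int(np.ceil(bulk_fraction * n))
        nonzero = np.flatnonzero(cc != 0)
        order = nonzero[np.lexsort((nonzero, np.abs(cc[nonzero])))]
        labels[order[: max(0, quota - int((cc == 0).sum()))]] = BULK
    else:
        raise ValueError("bulk_rule must be 'per_tail' or 'magnitude'")
    return labels


def _cc_with_components(a: np.ndarray, bulk_fraction: float,
                        bulk_rule: str) -> tuple[float, np.ndarray, np.ndarray]:
    """CC and labels, restricting to the largest component if disconnected."""
    n = a.shape[0]
    n_comp, comp = _graph_components(a > 0, directed=False)
    if n_comp == 1:
        cc = control_centrality(a)
        return synchronizability(a), cc, label_roles(cc, bulk_fraction, bulk_rule)
    warnings.warn(
        "state graph is disconnected; control centrality computed on the "
        "largest component, remaining sources labelled bulk",
        stacklevel=3,
    )
    sizes = np.bincount(comp)
    big = np.flatnonzero(comp == sizes.argmax())
    cc = np.zeros(n)
    labels = np.zeros(n, dtype=np.int8)
    if len(big) >= 3:
        sub_cc = control_centrality(a[np.ix_(big, big)])
        cc[big] = sub_cc
        labels[big] = label_roles(sub_cc, bulk_fraction, bulk_rule)
    s = synchronizability(a[np.ix_(big, big)]) if len(big) >= 2 else 0.0
    return s, cc, labels


def vcr_all(stack: ConnectivityStack, bulk_fraction: float = 0.10,
            bulk_rule: str = "per_tail") -> CCStack:
    """Virtual resection for every band and state of a connectivity stack.

    PLV matrices enter as weighted adjacency with the diagonal zeroed;
    no thresholding is applied before the deletion sweep.
    """
    n_bands, n_states, n, _ = stack.values.shape
    s = np.empty((n_bands, n_states))
    cc = np.empty((n_bands, n_states, n))
    labels = np.empty((n_bands, n_states, n), dtype=np.int8)
    for b in range(n_bands):
        for st in range(n_states):
            a = stack.values[b, st].copy()
            np.fill_diagonal(a, 0.0)
            s[b, st], cc[b, st], labels[b, st] = _cc_with_components(
                a, bulk_fraction, bulk_rule
            )
    return CCStack(
        s=s,
        cc=cc,
        labels=labels,
        band_indices=tuple(bd.index for bd in stack.bands),
        states=stack.states,
        node_indices=stack.node_indices,
    )
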