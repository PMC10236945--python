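"""Phase-locking-value (PLV) matrices for the two brain states.

For a source pair (j, k) the PLV is the modulus of the mean unit phasor
of the phase difference, taken over *all trials concatenated* within one
100 ms state window:

    PLV(j, k) = | mean_{trials, samples} exp(i (phi_j - phi_k)) |

so every value is estimated from n_trials x 100 ms of data.  Two states
are analysed: a pre-spike window centred 750 ms before the onset and a
spike-onset window centred at the onset itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BandDefinition

__all__ = ["StateWindow", "ConnectivityStack", "window_indices", "plv", "STATES"]

STATES = ("pre", "spike")


@dataclass(frozen=True)
class StateWindow:
    """A 100 ms analysis window fixed relative to the spike onset."""

    state: str                 # 'pre' | 'spike'
    center: float              # s relative to onset
    length: float = 0.100      # s

    @staticmethod
    def defaults() -> tuple["StateWindow", "StateWindow"]:
        return (StateWindow("pre", -0.750), StateWindow("spike", 0.0))


@dataclass
class ConnectivityStack:
    """Symmetric PLV matrices, one per (band, state), over SAN sources.

    ``values`` has shape (n_bands, 2, n, n) with state axis ordered
    ('pre', 'spike'); every matrix is symmetric with unit diagonal.
    """

    values: np.ndarray
    bands: tuple[BandDefinition, ...]
    states: tuple[str, str] = STATES
    n_trials: int = 0
    windows: tuple[StateWindow, ...] = field(default_factory=StateWindow.defaults)
    node_indices: np.ndarray | None = None  # valid-source index per node

    @property
    def n_nodes(self) -> int:
        return self.values.shape[-1]

    def matrix(self, band_index: int, state: str) -> np.ndarray:
        b = [bd.index for bd in self.bands].index(band_index)
        return self.values[b, self.states.index(state)]


def window_indices(
    w: StateWindow, fs: float, epoch_window: tuple[float, float] = (-1.0, 1.0)
) -> tuple[int, int]:
    """Half-open sample range of the state window inside the epoch.

    The range has length ``round(length * fs)`` and is centred at
    ``round((center - epoch_start) * fs)``.
    """
    length = int(round(w.length * fs))
    center = int(round((w.center - epoch_window[0]) * fs))
    start = center - length // 2
    stop = start + length
    n_epoch = int(round((epoch_window[1] - epoch_window[0]) * fs))
    if start < 0 or stop > n_epoch:
        raise ValueError(
            f"state window '{w.state}' [{start}, {stop}) falls outside the "
            f"epoch of {n_epoch} samples"
        )
    return start, stop


def plv(
    phases: np.ndarray,
    window: tuple[int, int],
    node_indices: np.ndarray | None = None,
) -> np.ndarray:
    """PLV matrix from phase epochs (trials, sources, time) in one window.

    Trials are concatenated before the single modulus is taken, exactly
    equivalent to averaging the per-trial *complex* sums.
    """
    a, b = window
    if b <= a:
        raise ValueError("empty state window")
    if phases.shape[0] < 1:
        raise ValueError("at least one trial is required")
    if node_indices is not None:
        phases = phases[:, np.asarray(node_indices, dtype=int), :]
    seg = phases[..., a:b]                      # (trials, n, L)
    n = seg.shape[1]
    z = np.exp(1j * seg).transpose(1, 0, 2).reshape(n, -1)  # concatenate trials
    m = z.shape[1]
    plv_mat = np.abs(z @ z.conj().T) / m
    plv_mat = np.clip(plv_mat, 0.0, 1.0)
    plv_mat = 0.5 * (plv_mat + plv_mat.T)       # enforce exact symmetry
    np.fill_diagonal(plv_mat, 1.0)
    return plv_mat
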