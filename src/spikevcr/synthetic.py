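"""Seeded generators of patient bundles and graph scenarios with ground truth.

The patient simulator emulates the statistical structure the pipeline
assumes in real source-space recordings: 1/f background noise at every
source, a spatially contiguous planted cluster carrying band-limited
oscillations phase-locked through a shared driver (with a coupling
strength that switches between a pre-spike and a spike-onset value in
windows locked to each catalogued onset), and a biphasic spike waveform
added at the planted sources.  Narrowband components are synthesised
spectrally (complex Gaussian coefficients confined to the band with
raised-cosine edges), which gives direct, monotone control of the
phase-locking value through the mixing coefficient kappa without
solving coupled oscillators.

Ground-truth role labels are never asserted analytically: they are
measured by running the control-centrality computation on the expected
adjacency of the generating model (construct, then measure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.fft import irfft, rfftfreq
from scipy.spatial import cKDTree

from .bundle import PatientBundle, ResectionMask, SourceGrid, SpikeCatalog
from .config import PipelineConfig, default_bands
from .resection import control_centrality, label_roles

__all__ = [
    "SimScenario",
    "GroundTruth",
    "make_grid",
    "simulate_patient",
    "generate_graph_scenario",
]

# named substreams so stages can be regenerated independently
_STREAMS = {"noise": 0, "onsets": 1, "graph": 2, "oscillation": 3, "cluster": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimScenario:
    """Generating conditions for one synthetic patient.

    Coupling strengths are mixing coefficients in [0, 1): a planted pair
    shares a fraction ``kappa**2`` of its narrowband variance with the
    common driver, so kappa controls the within-cluster PLV directly.
    """

    n_per_side: int = 13            # cubic lattice side; ~960 valid sources
    spacing: float = 5.0            # mm
    n_spikes: int = 30
    fs: float = 1000.0
    noise_exponent: float = 1.0     # 1/f^alpha background
    noise_amplitude: float = 1.0    # per-source RMS, arbitrary units
    cluster_size: int = 20
    planted_bands: tuple[int, int] = (6, 10)   # inclusive band-table indices
    kappa_pre: float = 0.80
    kappa_spike: float = 0.95
    kappa_background: float = 0.10
    osc_amplitude: float = 0.5      # per-band oscillation RMS
    spike_shape: str = "biphasic"   # Gaussian-derivative waveform
    spike_width: float = 0.070      # s, full width
    spike_amplitude: float = 10.0   # multiple of the background RMS
    mode: str = "step1"
    outcome: str = "favourable"
    seed: int = 0
    planted_cluster: Optional[np.ndarray] = None  # valid-source indices

    def validate(self) -> None:
        if self.n_per_side < 2:
            raise ValueError("n_per_side must be at least 2")
        b0, b1 = self.planted_bands
        if not 1 <= b0 <= b1 <= 12:
            raise ValueError("planted_bands must be a valid band-index interval")
        for k in (self.kappa_pre, self.kappa_spike, self.kappa_background):
            if not 0.0 <= k < 1.0:
                raise ValueError("coupling strengths must lie in [0, 1)")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be positive")


@dataclass
class GroundTruth:
    """What was planted, and what the graph oracle says about it."""

    planted_cluster: np.ndarray          # valid-source indices
    planted_bands: tuple[int, int]
    itinerary: str                       # e.g. 'D->D', from the oracle
    oracle_labels: dict = field(default_factory=dict)  # state -> label vector
    oracle_nodes: np.ndarray | None = None  # node set the oracle was run on
    cc: dict = field(default_factory=dict)  # graph scenarios: state/graph -> CC
    s: float | None = None


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def make_grid(n_per_side: int, spacing: float = 5.0) -> SourceGrid:
    """Cubic lattice with an ellipsoidal valid interior (grey-matter analogue).

    The ellipsoid is centred on the lattice with semi-axes (0.55, 0.50,
    0.48) of the cube edge, giving a mildly anisotropic solid interior.
    """
    if n_per_side < 2:
        raise ValueError("n_per_side must be at least 2")
    idx = np.arange(n_per_side)
    xx, yy, zz = np.meshgrid(idx, idx, idx, indexing="ij")
    lattice = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(float)
    positions = lattice * spacing
    c = (n_per_side - 1) / 2.0
    semi = np.array([0.55, 0.50, 0.48]) * (n_per_side - 1)
    r2 = (((lattice - c) / semi) ** 2).sum(axis=1)
    return SourceGrid(positions=positions, spacing=spacing, valid_mask=r2 <= 1.0)


def _grow_cluster(grid: SourceGrid, size: int) -> np.ndarray:
    """Deterministically grow a contiguous cluster from the grid centroid."""
    pos = grid.valid_positions
    if size > len(pos):
        raise ValueError("cluster larger than the number of valid sources")
    center = pos.mean(axis=0)
    seed_idx = int(np.argmin(((pos - center) ** 2).sum(axis=1)))
    tree = cKDTree(pos)
    radius = np.sqrt(3.0) * grid.spacing + 1e-6
    chosen = {seed_idx}
    # greedy accretion: always add the candidate neighbour nearest the seed
    frontier = set(tree.query_ball_point(pos[seed_idx], radius)) - chosen
    while len(chosen) < size:
        if not frontier:
            raise ValueError("cannot grow a connected cluster of this size")
        best = min(
            frontier,
            key=lambda i: (float(((pos[i] - pos[seed_idx]) ** 2).sum()), i),
        )
        chosen.add(best)
        frontier |= set(tree.query_ball_point(pos[best], radius)) - chosen
        frontier.discard(best)
    return np.array(sorted(chosen), dtype=int)


def _cluster_shell(grid: SourceGrid, cluster: np.ndarray) -> np.ndarray:
    """Valid sources 26-adjacent to the cluster but not inside it."""
    pos = grid.valid_positions
    tree = cKDTree(pos)
    radius = np.sqrt(3.0) * grid.spacing + 1e-6
    shell: set[int] = set()
    for i in cluster:
        shell |= set(tree.query_ball_point(pos[i], radius))
    return np.array(sorted(shell - set(int(i) for i in cluster)), dtype=int)


def _is_connected(grid: SourceGrid, members: np.ndarray) -> bool:
    from .san import connected_components

    return len(connected_components(members, grid)) == 1


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _synth_len(n_samples: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n_samples)


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                exponent: float, amplitude: float) -> np.ndarray:
    """1/f^alpha noise, each row normalised to the requested RMS.

    Synthesised spectrally in single precision at an FFT-friendly
    length, then cropped; precision is ample for a noise floor.
    """
    L = _synth_len(n_samples)
    f = rfftfreq(L)
    shape = np.zeros(len(f), dtype=np.float32)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_rows, len(f)))
        + 1j * rng.standard_normal((n_rows, len(f)))
    ).astype(np.complex64) * shape
    x = irfft(spec, n=L, axis=-1)[:, :n_samples]
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x * (amplitude / rms)


def _band_mask(n_samples: int, fs: float, low: float, high: float) -> np.ndarray:
    """Raised-cosine-edged spectral mask for one passband (1 Hz rolloff)."""
    f = rfftfreq(n_samples, d=1.0 / fs)
    mask = np.zeros_like(f)
    core = (f >= low) & (f <= high)
    mask[core] = 1.0
    for edge, sign in ((low, -1), (high, 1)):
        ramp = (f - edge) * sign
        sel = (ramp > 0) & (ramp < 1.0)
        mask[sel] = 0.5 * (1 + np.cos(np.pi * ramp[sel]))
    return mask


def _narrowband_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                      fs: float, low: float, high: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise rows, synthesised spectrally."""
    L = _synth_len(n_samples)
    mask = _band_mask(L, fs, low, high)
    nz = np.flatnonzero(mask > 0)  # draw coefficients only inside the band
    spec = np.zeros((n_rows, len(mask)), dtype=np.complex64)
    spec[:, nz] = (
        (
            rng.standard_normal((n_rows, len(nz)))
            + 1j * rng.standard_normal((n_rows, len(nz)))
        )
        * mask[nz]
    ).astype(np.complex64)
    x = irfft(spec, n=L, axis=-1)[:, :n_samples]
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    return x / rms


def _coupling_profile(n_samples: int, fs: float, onsets: np.ndarray,
                      kappa_pre: float, kappa_spike: float) -> np.ndarray:
    """Time course of the within-cluster coupling coefficient.

    Baseline ``kappa_pre``; around each onset the coupling ramps (100 ms
    raised cosine) to a ``kappa_spike`` plateau covering [-0.1, 0.3] s,
    so both analysis windows sit on flat coupling.
    """
    prof = np.full(n_samples, kappa_pre)
    ramp_n = int(round(0.100 * fs))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))  # 0 -> 1
    lo, hi = int(round(0.100 * fs)), int(round(0.300 * fs))
    for onset in onsets:
        a = int(onset) - lo - ramp_n
        prof[a : a + ramp_n] = kappa_pre + (kappa_spike - kappa_pre) * up
        prof[int(onset) - lo : int(onset) + hi] = kappa_spike
        b = int(onset) + hi
        prof[b : b + ramp_n] = kappa_spike - (kappa_spike - kappa_pre) * up
    return prof


def _spike_waveform(fs: float, width: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic Gaussian-derivative waveform with its |peak| at the onset.

    Returns (waveform, index of the onset sample within the waveform).
    """
    sigma = width / 6.0
    t = np.arange(int(round(-5 * sigma * fs)), int(round(3 * sigma * fs)) + 1) / fs
    x = t / sigma + 1.0                      # extremum of -x*exp(-x^2/2) at x = -1 -> t = 0...
    w = -x * np.exp(-0.5 * x ** 2)
    w = amplitude * w / np.abs(w).max()      # |w| peaks at t = 0
    onset_at = int(round(5 * sigma * fs))
    return w, onset_at


def _make_onsets(rng: np.random.Generator, n_spikes: int, fs: float) -> np.ndarray:
    """Onset samples with >= 4 s gaps and >= 3.4 s recording margins."""
    base = 3.5 + 4.3 * np.arange(n_spikes)
    jitter = rng.uniform(-0.1, 0.1, size=n_spikes)
    return np.round((base + jitter) * fs).astype(np.int64)


# ---------------------------------------------------------------------------
# ground-truth oracle
# ---------------------------------------------------------------------------

def _expected_adjacency(n_cluster: int, n_background: int, kappa: float,
                        kappa_background: float, rng: np.random.Generator,
                        baseline: float = 0.20) -> np.ndarray:
    """Expected coupling topology of the generating model in a planted band.

    Within-cluster weight is the shared-variance fraction kappa**2; all
    other pairs scatter around a weak floor reflecting residual
    background coupling and the finite-sample PLV estimation bias (the
    scatter matters: a perfectly uniform background would give every
    background node an identical role, which measured matrices never do).
    """
    n = n_cluster + n_background
    floor = max(baseline, kappa_background ** 2)
    a = rng.uniform(0.5 * floor, 1.5 * floor, size=(n, n))
    a = 0.5 * (a + a.T)
    a[:n_cluster, :n_cluster] = kappa ** 2
    np.fill_diagonal(a, 0.0)
    return a


def _oracle_itinerary(scn: SimScenario, n_background: int,
                      bulk_fraction: float = 0.10) -> tuple[str, dict]:
    """Measure the planted cluster's roles on the expected topology."""
    labels = {}
    for state, kappa in (("pre", scn.kappa_pre), ("spike", scn.kappa_spike)):
        a = _expected_adjacency(
            scn.cluster_size, n_background, kappa, scn.kappa_background,
            _rng(scn.seed, "graph"),
        )
        cc = control_centrality(a)
        labels[state] = label_roles(cc, bulk_fraction)
    chars = {1: "D", -1: "S", 0: "B"}
    itin = []
    for state in ("pre", "spike"):
        cluster_labels = labels[state][: scn.cluster_size]
        vals, counts = np.unique(cluster_labels, return_counts=True)
        itin.append(chars[int(vals[counts.argmax()])])
    return f"{itin[0]}->{itin[1]}", labels


# ---------------------------------------------------------------------------
# patient simulation
# ---------------------------------------------------------------------------

def simulate_patient(scn: SimScenario) -> tuple[PatientBundle, GroundTruth]:
    """Generate one synthetic patient bundle plus its ground truth."""
    scn.validate()
    grid = make_grid(scn.n_per_side, scn.spacing)
    n_valid = grid.n_valid
    if scn.planted_cluster is not None:
        cluster = np.unique(np.asarray(scn.planted_cluster, dtype=int))
        if not _is_connected(grid, cluster):
            raise ValueError("planted cluster is not spatially connected")
    else:
        cluster = _grow_cluster(grid, scn.cluster_size)
    shell = _cluster_shell(grid, cluster)

    onsets = _make_onsets(_rng(scn.seed, "onsets"), scn.n_spikes, scn.fs)
    n_samples = int(onsets[-1] + round(3.5 * scn.fs))

    # 1/f background at every source (chunked to bound memory)
    noise_rng = _rng(scn.seed, "noise")
    recording = np.empty((n_valid, n_samples), dtype=np.float32)
    for start in range(0, n_valid, 128):
        stop = min(start + 128, n_valid)
        recording[start:stop] = _pink_noise(
            noise_rng, stop - start, n_samples,
            scn.noise_exponent, scn.noise_amplitude,
        )

    # band-limited coupled oscillations in the planted bands
    osc_rng = _rng(scn.seed, "oscillation")
    bands = {b.index: b for b in default_bands()}
    planted = [bands[i] for i in range(scn.planted_bands[0], scn.planted_bands[1] + 1)]
    kappa_t = _coupling_profile(
        n_samples, scn.fs, onsets, scn.kappa_pre, scn.kappa_spike
    )
    mix_shared = kappa_t
    mix_indep = np.sqrt(1.0 - kappa_t ** 2)
    k_bg = scn.kappa_background
    bg_indep = np.sqrt(1.0 - k_bg ** 2)
    background = np.setdiff1d(np.arange(n_valid), cluster)
    driver_sum = np.zeros(n_samples)
    for band in planted:
        driver = _narrowband_noise(osc_rng, 1, n_samples, scn.fs, band.low, band.high)[0]
        driver_sum += driver
        indep = _narrowband_noise(
            osc_rng, len(cluster), n_samples, scn.fs, band.low, band.high
        )
        recording[cluster] += (
            scn.osc_amplitude * (mix_shared * driver + mix_indep * indep)
        ).astype(np.float32)
    # background sources: constant weak coupling to the drivers plus
    # independent in-band noise (one spectral draw per source and band)
    for start in range(0, len(background), 128):
        rows = background[start : start + 128]
        indep = np.zeros((len(rows), n_samples))
        for band in planted:
            indep += _narrowband_noise(
                osc_rng, len(rows), n_samples, scn.fs, band.low, band.high
            )
        recording[rows] += (
            scn.osc_amplitude * (k_bg * driver_sum + bg_indep * indep)
        ).astype(np.float32)

    # spike waveform at the planted sources
    wave, onset_at = _spike_waveform(
        scn.fs, scn.spike_width, scn.spike_amplitude * scn.noise_amplitude
    )
    for onset in onsets:
        a = int(onset) - onset_at
        recording[cluster, a : a + len(wave)] += wave.astype(np.float32)

    resection = None
    if scn.mode == "step1":
        resection = ResectionMask(np.concatenate([cluster, shell]))

    config = PipelineConfig(rng_seed=scn.seed)
    bundle = PatientBundle(
        grid=grid,
        recording=recording,
        spikes=SpikeCatalog(onsets=onsets, fs=scn.fs),
        resection=resection,
        mode=scn.mode,
        outcome=scn.outcome,
        patient_id=f"synthetic-{scn.seed}",
        config_snapshot=config.to_json(),
    )

    itinerary, labels = _oracle_itinerary(scn, n_background=len(shell))
    truth = GroundTruth(
        planted_cluster=cluster,
        planted_bands=scn.planted_bands,
        itinerary=itinerary,
        oracle_labels=labels,
        oracle_nodes=np.concatenate([cluster, shell]),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# graph-level scenarios
# ---------------------------------------------------------------------------

def generate_graph_scenario(
    n: int,
    planted_size: int,
    seed: int = 0,
    attach_strength: float = 0.05,
    bulk_fraction: float = 0.10,
) -> tuple[np.ndarray, GroundTruth]:
    """Random weighted background graph plus a planted near-clique.

    The clique is attached to the background with ``attach_strength``
    (0 disconnects it, making whole-graph synchronizability zero).
    Truth labels are obtained by running the control-centrality
    computation on the constructed graph, never asserted analytically.
    """
    if planted_size >= n:
        raise ValueError("planted_size must be smaller than n")
    rng = _rng(seed, "graph")
    a = rng.uniform(0.02, 0.15, size=(n, n))
    a = 0.5 * (a + a.T)
    a[:planted_size, :planted_size] = rng.uniform(
        0.7, 0.9, size=(planted_size, planted_size)
    )
    a[:planted_size, :planted_size] = 0.5 * (
        a[:planted_size, :planted_size] + a[:planted_size, :planted_size].T
    )
    a[:planted_size, planted_size:] = attach_strength
    a[planted_size:, :planted_size] = attach_strength
    np.fill_diagonal(a, 0.0)

    truth = GroundTruth(
        planted_cluster=np.arange(planted_size),
        planted_bands=(0, 0),
        itinerary="",
        s=None,
    )
    if attach_strength > 0:
        cc = control_centrality(a)
        truth.cc["graph"] = cc
        truth.oracle_labels["graph"] = label_roles(cc, bulk_fraction)
        from .resection import synchronizability

        truth.s = synchronizability(a)
    else:
        from .resection import synchronizability

        truth.s = synchronizability(a)
    return a, truth
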