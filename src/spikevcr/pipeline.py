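"""End-to-end orchestration: recording in, candidate cluster out.

Stages run in a fixed order — preprocessing, spike-associated-network
selection, two-state connectivity, virtual resection, cluster search,
and (when surgical information is available) outcome evaluation.  The
resection mask is consulted before evaluation only in step1 mode, and
the outcome label only at the evaluation stage itself, mirroring the
blinded study design.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import preprocess, san as san_mod
from .bundle import PatientBundle
from .clusters import ClusterCandidate, SearchResult, sequential_search
from .config import BROADBAND, BandDefinition, PipelineConfig
from .connectivity import STATES, ConnectivityStack, StateWindow, plv, window_indices
from .evaluation import OutcomeRecord, classify, locate_cluster
from .resection import CCStack, vcr_all

__all__ = ["PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException) -> None:
        super().__init__(f"stage '{stage}': {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineResult:
    """All per-stage artifacts of one pipeline run."""

    san: san_mod.SANSelection
    connectivity: ConnectivityStack
    cc_stack: CCStack
    search: SearchResult
    candidate: Optional[ClusterCandidate]
    record: Optional[OutcomeRecord] = None
    log: list = field(default_factory=list)  # (stage, seconds, note)

    @property
    def emergence_threshold(self) -> Optional[float]:
        return self.candidate.threshold if self.candidate else None


def _timed(log: list, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def note(self, text: str) -> None:
            self._note = text

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(stage, exc) from exc
            log.append((stage, time.perf_counter() - self.t0,
                        getattr(self, "_note", "")))

    return _Ctx()


def _band_epochs(
    rows: np.ndarray,
    band: BandDefinition,
    bundle: PatientBundle,
    config: PipelineConfig,
) -> preprocess.BandEpochs:
    """Band-limited spike-locked epochs for a subset of sources.

    ``filter_stage='continuous'`` filters the full-length rows before
    epoching; ``'epoch'`` cuts epochs extended by the padding margin,
    filters those, and crops — equal at interior samples by linearity.
    """
    fs = bundle.spikes.fs
    kernel = preprocess.design_zero_phase_bandpass(band, fs, config.filter_order)
    w0, w1 = config.epoch_window
    if config.filter_stage == "continuous":
        filtered = preprocess.two_pass_filter(rows, kernel, axis=-1)
        return preprocess.epoch(filtered, bundle.spikes, (w0, w1), band=band)
    pad = config.pad_seconds
    ext = preprocess.epoch(rows, bundle.spikes, (w0 - pad, w1 + pad), band=band)
    filtered = preprocess.two_pass_filter(ext.values, kernel, axis=-1)
    crop = int(round(pad * fs))
    return preprocess.BandEpochs(
        values=filtered[..., crop : filtered.shape[-1] - crop],
        fs=fs,
        band=band,
        epoch_window=(w0, w1),
    )


def _broadband_onset_amplitudes(
    bundle: PatientBundle, config: PipelineConfig
) -> np.ndarray:
    """(trials, sources) broadband |amplitude| at (or near) each onset."""
    band = BandDefinition(0, "broadband", *BROADBAND)
    fs = bundle.spikes.fs
    onsets = bundle.spikes.onsets
    n_valid = bundle.recording.shape[0]
    amp = np.empty((len(onsets), n_valid))
    half = int(round(0.010 * fs))
    for start in range(0, n_valid, 128):  # chunked: full-length filtering is wide
        stop = min(start + 128, n_valid)
        rows = np.asarray(bundle.recording[start:stop])
        preprocess._check_length(rows, config, fs)
        kernel = preprocess.design_zero_phase_bandpass(band, fs, config.filter_order)
        filtered = preprocess.two_pass_filter(rows, kernel, axis=-1)
        if config.amplitude_mode == "onset":
            amp[:, start:stop] = np.abs(filtered[:, onsets]).T
        else:
            windows = np.stack(
                [
                    np.abs(filtered[:, o - half : o + half + 1]).max(axis=-1)
                    for o in onsets
                ]
            )
            amp[:, start:stop] = windows
    return amp


def run_pipeline(
    bundle: PatientBundle, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full protocol on one patient bundle."""
    config = config or PipelineConfig()
    config.validate()
    bundle.validate()  # step1 without resection fails here, before any work
    log: list = []
    fs = bundle.spikes.fs

    with _timed(log, "san_builder") as ctx:
        amp = _broadband_onset_amplitudes(bundle, config)
        ranks = san_mod.rank_from_amplitude(amp)
        survivors = san_mod.persistent_sources(
            ranks, config.san_top_k, config.san_persistence
        )
        selected = san_mod.top_fraction(
            survivors,
            ranks,
            config.san_top_fraction,
            quota_base=config.quota_base,
            rank_aggregate=config.rank_aggregate,
        )
        resection = bundle.resection if bundle.mode == "step1" else None
        assembled = san_mod.assemble_san(selected, resection, bundle.mode)
        assembled.step_counts.update(
            persistent=len(survivors), top_fraction=len(selected),
            assembled=assembled.n_members,
        )
        san = san_mod.prune_islands(assembled, bundle.grid, config.san_min_island)
        ctx.note(f"SAN size {san.n_members}")

    with _timed(log, "connectivity") as ctx:
        rows = np.asarray(bundle.recording[san.member_indices])
        state_windows = tuple(
            StateWindow(s, config.state_centers[s], config.state_length)
            for s in STATES
        )
        n = san.n_members
        values = np.empty((len(config.band_table), len(STATES), n, n))
        for bi, band in enumerate(config.band_table):
            epochs = _band_epochs(rows, band, bundle, config)
            phases = preprocess.instantaneous_phase(epochs)
            for si, w in enumerate(state_windows):
                rng_idx = window_indices(w, fs, config.epoch_window)
                values[bi, si] = plv(phases.values, rng_idx)
        stack = ConnectivityStack(
            values=values,
            bands=tuple(config.band_table),
            n_trials=epochs.values.shape[0],
            windows=state_windows,
            node_indices=san.member_indices,
        )
        ctx.note(f"{len(config.band_table)} bands x {len(STATES)} states")

    with _timed(log, "virtual_resection"):
        cc_stack = vcr_all(stack, config.bulk_fraction, config.bulk_rule)

    with _timed(log, "cluster_search") as ctx:
        pairs = bundle.grid.adjacency_pairs(san.member_indices)
        search = sequential_search(cc_stack, pairs, config)
        if search.found:
            ctx.note(
                f"candidate at threshold {search.candidate.threshold:.2f}, "
                f"min size {search.candidate.min_size_level}"
            )
        else:
            ctx.note("no cluster emerged")

    record = None
    if search.found and bundle.resection is not None:
        with _timed(log, "evaluation") as ctx:
            location, overlap = locate_cluster(
                search.candidate, bundle.resection, config.inside_fraction
            )
            record = OutcomeRecord(
                patient_id=bundle.patient_id,
                outcome=bundle.outcome,
                location=location,
                overlap=overlap,
            )
            if bundle.outcome in ("favourable", "unfavourable"):
                record.classification, record.model_performance = classify(
                    bundle.outcome, location
                )
            else:
                warnings.warn(
                    "outcome unknown; cluster located but not classified",
                    stacklevel=2,
                )
            ctx.note(f"cluster {location}, overlap {overlap:.2f}")

    return PipelineResult(
        san=san,
        connectivity=stack,
        cc_stack=cc_stack,
        search=search,
        candidate=search.candidate,
        record=record,
        log=log,
    )
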