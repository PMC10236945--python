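# Methods

This note records the models, parameter choices and numerical decisions
behind `spikevcr`, including the points where the protocol left the
design genuinely open.

## Scope and contract

The package starts at *source-space* time series: a (sources × time)
recording on a regular 5 mm grid, a catalog of spike-onset samples, and
optionally a resection mask (a set of source indices).  Everything
upstream — sensor acquisition, artifact removal, head modelling,
beamforming, MRI segmentation — is out of scope.  Two study designs are
supported: `step1`, where the resection cavity is known and forced into
the analysis network, and `step2`, where the selection stays blind to
it.  The outcome label and the resection mask travel with the patient
bundle but are consulted only where the design allows: the mask at
network assembly (step1 only) and at evaluation; the outcome at
evaluation only.  This is enforced by the pipeline's stage interfaces,
not by convention.

## Preprocessing

* **Filterbank.** Twelve passbands: 4–8, 8–14, 15–30, 30–45, 45–55,
  65–75, 75–85, 85–95, 95–105, 105–115, 125–135, 135–145 Hz.  The gaps
  at 55–65 and 115–125 Hz avoid power-line harmonics in the kind of
  recording the protocol targets.  Each band uses a 1501-tap
  linear-phase FIR (order 1500, Hamming window) applied forward and
  backward, so the net phase is zero and the effective magnitude
  response is the squared single-pass response.  Two-pass application
  is implemented as one convolution with the self-convolved kernel,
  which is exactly equivalent for a symmetric kernel and allows
  overlap-add FFT convolution on long recordings.
* **Filtering stage.** Filtering is applied to the *continuous*
  recording before epoching (`filter_stage='continuous'`); the 2 s
  padding requirement is honoured by demanding that much real recording
  on each side of every epoch rather than by padding short epochs,
  since a 2 s epoch cannot supply the transient of a 1501-tap two-pass
  filter from within itself.  The alternative (`'epoch'`) filters
  epochs extended by the same margin and crops; both orders agree at
  interior samples to numerical precision (tested).
* **Epochs and phase.** Epochs span [−1, 1) s with the onset at index
  `fs`; windows are half-open in samples and all indices are 0-based.
  Instantaneous phase is the angle of the analytic (Hilbert) signal per
  2 s epoch.  Both analysis windows lie ≥ 0.65 s from the epoch edges,
  outside the transform's edge-distortion zone.  The narrow 10 Hz gamma
  bands keep the window method's natural roll-off; no attempt is made
  to sharpen transitions beyond the stated order.

## Spike-associated network

Per spike, sources are ranked by broadband (2–55 Hz) |amplitude| at the
single onset sample (a ±10 ms maximum is available as
`amplitude_mode='window'` because the spike peak may lag the marked
onset); ties break by source index.  Sources within the top
`san_top_k = 1000` ranks in at least ⌈0.75 · n_trials⌉ trials survive;
survivors are scored by mean rank across trials (median optional) and
the best ⌈0.05 · n_total⌉ are kept.  The 5 % quota is taken against the
*total* candidate count by default — with ~5500 candidates this gives
~275 selected, consistent with networks of 500–600 sources once the
resection union is added; a survivor-based quota is available
(`quota_base='survivors'`).  Spatial components (26-neighbourhood:
Euclidean distance ≤ √3 × spacing) smaller than 5 sources are pruned.

## Connectivity

PLV is computed as a single modulus over all trials concatenated within
one 100 ms state window, i.e. every estimate uses n_trials × 100 ms of
data; this operational definition (rather than a sliding smoothed
variant) is the implemented and tested contract.  The two states are
centred at −750 ms and 0 ms.  Matrices are symmetric with unit
diagonal; the diagonal is zeroed before any graph computation.

## Virtual resection

Synchronizability is the combinatorial-Laplacian eigenratio
S = λ₂/λ_max, the master-stability convention: deletion of a node that
*raises* S is desynchronizing, matching the sign convention of
CC_i = (S_i − S)/S.  Eigenvalues come from a dense symmetric solver
with a 1e-12 zero tolerance for identifying λ₂; S = 0 on disconnected
graphs, where CC is undefined (an error for a direct call).  Inside the
band/state sweep a disconnected graph — a degenerate input for dense
PLV matrices — is handled by computing on the largest component and
assigning CC = 0 / bulk elsewhere, with a warning.  PLV matrices enter
unthresholded.  Bulk labelling takes, per sign tail, the
⌈(bulk_fraction/2) · n⌉ values of smallest magnitude (quota capped by
tail occupancy, never reassigned); reading "10 % closest to zero" as a
single magnitude quota is available via `bulk_rule='magnitude'`.

## Cluster search

A (source, band) cell is *active* at threshold t iff the source's |CC|
is within the top ⌈t·n⌉ magnitudes in **both** states ("two tails" read
as magnitude ranking; per-state union is available via
`active_rule='either'`).  Connectivity on the source × band lattice is
26-neighbour spatial adjacency within a band plus same-source adjacency
across consecutive band *indices* — bands 5/6 and 10/11 are adjacent
despite the spectral gaps.  Components must share one itinerary.  A
component qualifies when ≥ `min_sources` of its sources hold the
itinerary over ≥ 4 consecutive bands; the reported cluster is the
longest such band interval held by every reported member (ties: more
members, then the lower band).  The sweep runs t = 0.01 … 1.00 in 0.01
steps at minimum size 15, then 10, then 5; exhaustion returns a typed
no-solution, never an exception.  If several clusters emerge at the
same threshold the one with most members wins (ties: larger mean |CC|,
then lower first band).  All nine itineraries may form clusters; the
itinerary is always logged.

Role symbols follow the CC sign semantics throughout: `D`
(desynchronizing) for CC > 0, `S` (synchronizing) for CC < 0, `B` for
bulk, so a `D->D` cluster is one whose removal would make the network
easier to synchronize in both states.

## Evaluation

The in/out verdict uses majority overlap: `in` iff
|cluster ∩ resection| / |cluster| ≥ 0.5.  The protocol reports verdicts
but no explicit rule — borderline clusters at the cavity margin are a
recognized judgment call — so the overlap fraction is always carried in
the output for auditing under other thresholds.  Classification:
in+favourable = TP, in+unfavourable = FP, out+unfavourable = TN,
out+favourable = FN; TP and TN are model successes.  Ratios with zero
denominators are reported as undefined, never 0; rounding (2 decimals
for ratios, 4 for p) happens only at presentation.  The Fisher test is
two-sided with the probability-mass convention, validated against
brute-force enumeration over fixed margins.

## Synthetic data

The simulator emulates the statistical structure the pipeline assumes,
not the biophysics: no forward model, sensor noise or head geometry.

* **Grid.** Cubic lattice, 5 mm spacing, ellipsoidal valid interior
  (semi-axes 0.55/0.50/0.48 of the cube edge).  The default 13³ lattice
  yields 959 valid sources — a deliberately reduced desk-scale analogue
  of the 5000–6000-source clinical grids.
* **Spikes.** 30 onsets by default, ≥ 4 s apart with ±0.1 s jitter, so
  epochs plus the 2 s filter margin never overlap or touch the
  recording boundaries.  The spike waveform is a biphasic
  Gaussian-derivative, 70 ms full width, amplitude 10× the background
  RMS, aligned so its magnitude peak sits on the onset sample — making
  onset-amplitude ranking well defined.
* **Oscillations.** Per planted band, cluster members mix a shared
  narrowband driver with independent narrowband noise,
  x = κ(t)·d + √(1−κ²)·e; κ gives direct monotone control of PLV.
  κ is 0.80 at baseline (the pre-spike state) and ramps (100 ms raised
  cosine) to a 0.95 plateau covering [−0.1, 0.3] s around each onset,
  so both analysis windows sit on flat coupling.  Background sources
  carry weak driver coupling (κ = 0.10) plus independent in-band noise.
  Narrowband components are synthesised spectrally (complex Gaussian
  coefficients confined to the band, 1 Hz raised-cosine edges) in
  single precision — ample for a noise process and several-fold faster
  than FIR synthesis.  1/f background noise (exponent 1) underlies all
  sources.  These coupling values are calibration choices for a
  realistic-looking contrast, not measured facts about any cohort.
* **Ground truth.** Role labels and the planted itinerary are never
  asserted analytically: they are measured by running the
  control-centrality computation on the *expected* coupling topology of
  the generating model (within-cluster weight κ², background scattered
  around a floor reflecting residual coupling and PLV estimation bias).
  A perfectly uniform background would give every background node an
  identical role, which measured matrices never do, so the floor is
  jittered.  With the default 20-source cluster the oracle yields D→D;
  clusters much smaller than the per-tail bulk quota can be relabelled
  bulk, which is a property of the labelling rule, not a simulator bug.
* **Randomness.** One seed feeds named substreams (noise, onsets,
  graph, oscillation, cluster) so stages can be regenerated
  independently; everything is bit-reproducible under a fixed seed.

What passing the recovery test shows — and what it does not: the
pipeline can localize a contiguous, band-limited, phase-coupled
structure against 1/f background at realistic SNR; it says nothing
about beamformer leakage, artifact contamination, or inter-patient
variability in real recordings.

## Problem sizes

The bundled tests and the acceptance script run the full pipeline on
five simulated patients of ~960 sources, 30 spikes and ~132 s of
recording at 1000 Hz each, and verify the graph measures by exhaustive
deletion on graphs of up to 12 nodes and the cluster search against
flood-fill enumeration on fields of ≤ 200 cells.  These sizes were
chosen as the smallest at which every qualitative feature of the
full-scale problem (grid contiguity, quota arithmetic, band adjacency,
state contrast) is still exercised.

## Known limitations

* The cluster-size count refers to sources holding the itinerary over
  the reported band interval; a protocol could also count every source
  of the component, which would report larger sizes.
* The per-patient results of the original clinical cohort are not
  reproducible without the (unavailable) recordings; the bundled cohort
  CSV carries only the published per-patient outcome records, and the
  pipeline's quantitative behaviour is validated on synthetic patients
  instead.
* Registration error between functional and anatomical spaces (several
  mm in practice) is not modelled; the bundle records grid spacing but
  no registration error model.
* Multi-node simultaneous resections and optimization over candidate
  sets are out of scope.
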