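# spikevcr

Personalized *virtual cortical resection* modelling of interictal spike
networks from source-space electrophysiology.

Epilepsy surgery fails in a substantial fraction of patients, usually
because the epileptogenic zone was localized inaccurately or resected
incompletely.  `spikevcr` implements an individual, data-driven protocol
that proposes a single candidate brain volume for resection from a
patient's spike-locked source-space recording (e.g. beamformed MEG),
and scores the proposal against the surgical outcome.  It is aimed at
researchers studying epileptic network dynamics and in-silico surgery
planning.

## The model

Starting from a continuous recording on a regular 5 mm source grid with
a catalog of interictal spike onsets, the pipeline:

1. **Spike-associated network (SAN).**  Sources are ranked per spike by
   broadband (2–55 Hz) |amplitude| at the onset sample; sources ranked
   within the top 1000 in ≥ 75 % of spikes are kept; the best 5 % by
   mean rank form the network (step1 designs additionally force in the
   resection cavity); spatial islands of < 5 sources are pruned.
2. **Two-state connectivity.**  Recordings are band-passed into 12
   bands (θ, α, β and nine 10 Hz gamma sub-bands up to 145 Hz) with a
   1501-tap zero-phase Hamming FIR, epoched to [−1, 1) s around each
   onset, and the phase-locking value is computed over all spikes
   concatenated within two 100 ms windows: a *pre-spike* state centred
   at −750 ms and a *spike-onset* state centred at 0,

       PLV(j,k) = | ⟨ exp( i(φ_j − φ_k) ) ⟩_{trials × samples} | .

3. **Virtual resection.**  Each PLV matrix is a weighted graph with
   synchronizability S = λ₂/λ_max of its Laplacian.  Deleting source
   *i* and recomputing gives the control centrality
   CC_i = (S_i − S)/S: positive values mark desynchronizing sources,
   negative synchronizing, and the 10 % (5 % per tail) nearest zero are
   *bulk*.
4. **Cluster search.**  Each source carries an itinerary per band (its
   role before → at the spike, e.g. D→D).  A sweep admits sources from
   the largest |CC| down in 1 % steps; the first spatially contiguous
   cluster of ≥ 15 sources sharing one itinerary over ≥ 4 consecutive
   bands is the candidate (the minimum size falls back 15 → 10 → 5 if
   none emerges).
5. **Evaluation.**  A candidate inside the resection cavity of a
   seizure-free patient (or outside, in a patient with persisting
   seizures) counts as a model success; cohort accuracy, sensitivity,
   specificity and a two-sided Fisher exact test are reported.

Because no public recording of this kind exists, the package ships a
seeded simulator (`spikevcr.synthetic`) producing patient bundles with
1/f noise, a contiguous planted cluster whose band-limited phase
coupling switches between the two states, spike waveforms, and oracle
ground truth.

## Worked example

```bash
$ printf 'n_per_side: 7\ncluster_size: 8\nn_spikes: 10\n' > scn.yaml
$ spikevcr simulate --scenario scn.yaml --seed 3 --out tiny.h5
wrote tiny.h5 (121 sources, 10 spikes) and tiny.truth.json
$ spikevcr run tiny.h5 --out run1
candidate: D->D size 5 bands 6,7,8,9 threshold 0.48
```

The run found a desynchronizing→desynchronizing cluster of 5 sources
locked across bands 6–9 (65–105 Hz), which emerged once the 48 % of
sources with the largest |CC| were admitted — at this toy scale the
minimum-size ladder fell back to 5.  `run1/result.csv` holds the same
information as one cohort row, `run1/candidate.tsv` the member
coordinates, and `tiny.truth.json` the planted cluster for comparison.

Scoring a cohort of per-patient records (here the bundled example
cohort of 24 paediatric surgery cases):

```bash
$ spikevcr evaluate --records src/spikevcr/data/example_cohort.csv
sample,n,tp,fn,tn,fp,accuracy,sensitivity,specificity,fisher_p,successes
step1,14,8,2,3,1,0.785...,0.8,0.75,0.0949...,11
step2,10,2,1,6,1,0.8,0.666...,0.857...,0.1833...,8
all,24,10,3,9,2,0.791...,0.769...,0.818...,0.0122...,19
```

i.e. the model verdict agreed with the surgical outcome in 19 of 24
patients (accuracy 0.79, sensitivity 0.77, specificity 0.82, Fisher
p = 0.0123).

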