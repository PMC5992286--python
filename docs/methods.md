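# Methods

This note documents the models and numerical choices behind `mlfc`: the
connectivity estimators, the OMST filter, the multilayer metrics, the
classification harness, and — because every empirical claim in the test
suite rests on it — the synthetic cohort generator.

## Signal model and filterbank

Recordings are epoched multichannel series (epochs × ROIs × samples) at
sampling rate `fs`. Analysis is strictly per epoch: epochs are treated
as independent trials, filtered and Hilbert-transformed separately, and
estimator values are averaged across epochs (arithmetic mean of
per-epoch values).

The filterbank is a zero-phase (forward–backward) 3rd-order Butterworth
band-pass for each of the seven canonical bands δ(0.5–4), θ(4–8),
α₁(8–10), α₂(10–13), β₁(13–20), β₂(20–30), γ₁(30–45 Hz). Zero-phase
filtering preserves instantaneous phase relations, which the phase
estimators require. After the Hilbert transform, 0.5 s is trimmed from
each epoch end before any estimator sees the data; this absorbs the
`filtfilt` and Hilbert edge transients. Epoch length is configurable
(default 4 s); for δ-band phase–amplitude coupling, epochs of 6–8 s are
noticeably cleaner because the second filtering stage (envelope in the
δ range) needs several slow cycles per epoch.

## Connectivity estimators

With analytic phases φ(t) and envelopes A(t):

* `PLV  = (1/T)|Σ_t exp(i(φ_X − φ_Y))|` — phase locking, in [0, 1].
* `iPLV = (1/T)|Im Σ_t exp(i(φ_X − φ_Y))|` — keeps only the quadrature
  component, hence blind to zero-lag coupling; for a constant lag Δ,
  PLV = 1 and iPLV = |sin Δ| exactly. iPLV ≤ PLV always.
* `CorrEnv` — absolute Pearson correlation of envelopes,
  non-orthogonalized. The absolute value is a deliberate choice:
  downstream topological filtering and the participation coefficient
  require non-negative weights, and the sign of envelope correlation is
  not used anywhere in the pipeline.

Cross-frequency coupling, for an ordered band pair (LF, HF):

* *Phase–amplitude coupling (PAC)*: band-pass x in LF → φ_LF; band-pass
  y in HF → envelope A_HF; band-pass A_HF **within the LF range** →
  Hilbert → φ′; the PAC weight is the phase locking (iPLV by default,
  PLV available) of (φ_LF, φ′). If the HF envelope is near-constant
  (coefficient of variation < 0.05) the modulation phase is undefined
  and an error is raised rather than returning noise.
* *Cross-frequency envelope correlation*: |Pearson r| between the
  band-a envelope of x and the band-b envelope of y.

Both cross-frequency estimators are directional (which node supplies the
slow phase matters). Undirected graph entries take the **max** over the
two direction assignments — the stronger modulation defines the edge —
with an arithmetic-mean variant behind a switch.

Per subject and estimator this yields 28 single-layer graphs (7 intra +
21 cross, in fixed order: bands ascending, then pairs in lexicographic
band-index order), each N×N, symmetric, non-negative, zero-diagonal.

## Multilayer graph, OMST, MPC, comodulograms

The 28 layers assemble into a flattened (7N)×(7N) supra-adjacency
matrix: intra layers on the diagonal blocks, the CFC layer of band pair
(i, j) in off-diagonal block (i, j) and its transpose in (j, i). No
artificial inter-layer links between homologous ROIs are added.

**OMST filtering.** On distances d = 1/w (matching the path-length
convention of global efficiency; a 1−w variant is a config switch),
round r extracts the minimum spanning tree of the graph restricted to
edges unselected in rounds < r — Kruskal with a deterministic tie-break
(smaller distance first, then lower node indices). After each round the
aggregate of all rounds is scored by `J = GE − Cost`, where GE is the
weighted global efficiency (mean inverse shortest-path length over
ordered pairs, unreachable pairs contributing 0, Dijkstra on the
retained edges) and Cost is the retained fraction of total edge weight.
Extraction stops when the remaining edges no longer span the graph or
when J has declined for 5 consecutive rounds (the J curve is concave in
practice; the patience guard is cheap insurance against local jitter),
and the aggregate at the first J-maximum is returned. On 5-node graphs
the returned peak agrees with exhaustive enumeration of all
"first k orthogonal MSTs" candidates (tested over 100 random
instances against a networkx oracle).

**MPC.** On the 28 OMST-filtered layers, with binary degrees k_i[λ] and
o_i = Σ_λ k_i[λ]:

    MPC_i = M/(M−1) · (1 − Σ_λ (k_i[λ]/o_i)²),  M = 28

so MPC_i = 0 when all of node i's retained edges sit in one layer and 1
when they spread evenly. Nodes with o_i = 0 are assigned 0. A
weighted-strength variant exists behind a flag; binary degree is the
default because OMST already encodes weight information in the edge
selection. Dense (unfiltered) layers are accepted with a warning.

**Comodulograms.** The multilayer OMST runs on the flattened matrix as
a single graph; retained edges are counted per band-pair block and
normalized to sum to 1, giving a 7×7 upper-triangular probability
table (diagonal = intra layers). Subject tables average into group
comodulograms.

## Classification

Three feature routes feed an SVM with RBF kernel (C = 1,
gamma = "scale"; hyperparameters are reproducible defaults, with
leakage-safe in-fold tuning possible but off by default):

* **edge** — upper-triangle edge weights of the fully weighted graph
  (N(N−1)/2 = 4,005 per single layer at N = 90; 28× that for the
  multilayer concatenation). Inside each training fold, features are
  z-scored and ranked by greedy mRMR: first pick argmax MI(f; y), then
  iteratively argmax [MI(f; y) − mean MI(f, picked)], with MI estimated
  on 8-bin quantile-discretized values; the top 15 enter the SVM. The
  15 features most frequent across folds (ties: better mean rank, then
  id) are reported as the consensus biomarker.
* **tensor** — the OMST-filtered graph as a 2-D tensor, projected by
  tensor subspace analysis: alternating generalized eigenproblems learn
  row/column bases U (N×6) and V (N×6) that keep same-class graphs
  close (within-class affinity 1, between-class 0); each basis is then
  QR-orthonormalized, which leaves the subspace unchanged and makes the
  full-rank limit exactly invertible. Features are vec(UᵀWV), 36 per
  graph. Five alternations suffice; a small ridge stabilizes the
  generalized eigensolve.
* **mpc** — the N per-node MPC values, ranked/selected like edges.

Validation: leave-one-out (metrics from the pooled confusion matrix)
and stratified, seeded 5-fold (mean ± sd of per-fold metrics).
Stratification is a deliberate choice for small cohorts. Everything
data-dependent — scaling, ranking, TSA fitting — is fitted on the
training fold only; a dedicated test corrupts held-out labels and
verifies bitwise-identical fold artifacts. Sensitivity is defined on
group 2 (the patient group).

## Synthetic cohorts

Each ROI channel is unit-variance 1/f¹ noise (spectrally shaped white
noise; the exponent is configurable) plus √snr times the planted
components (snr default 3, a clearly-detectable-but-noisy regime).
Planted components per coupling mode:

* **intra** — both signals share one smooth frequency-modulated carrier
  phase whose instantaneous frequency drifts slowly (low-passed noise
  through tanh) and stays within the central 60% of the band, with
  independent slow amplitude envelopes (low-passed noise, cutoff
  min(1 Hz, lo/2), clipped positive). Signal 2 mixes the lag-shifted
  locked component at weight `strength` with an independent narrowband
  realization at `1 − strength`. The FM construction matters: carriers
  built from the phase of filtered noise have phase slips that broaden
  the spectrum, so re-filtering on the analysis side distorts the
  planted phase (locked-pair PLV ≈ 0.97 instead of ≈ 1) and leaks
  modulation into neighbouring bands. Independent envelopes keep pure
  phase coupling out of the envelope estimator (tested against its
  Monte-Carlo null).
* **pac** — the HF series is (1 + m·cos(φ_LF − lag)) times a
  unit-envelope FM carrier, plus an unmodulated narrowband HF floor
  (weight 0.4). The floor exists because the phase of the filtered
  envelope is perfectly defined for *any* m > 0 in a noise-free signal,
  which would make the estimator saturate rather than grow with m; with
  the floor the response is monotone over m ∈ {0, .25, .5, .75, 1}
  (Spearman ρ = 1 in the acceptance suite) while m = 0.9 still scores
  ≈ 0.85. `noise_floor=0` plants the stated envelope exactly.
* **env** — both signals' envelopes mix an own and a shared slow
  fluctuation with weights √(1−ρ) and √ρ, so the planted envelope
  correlation equals ρ on the correlation scale (a linear mix would
  bury small ρ under the rectified-null floor).

Subject-level strengths jitter around plan values (truncated normal,
sd 0.05); group-2 strengths shift by the planned delta. Within a
subject, PAC edges sharing a modulator ROI reuse one LF rhythm per
(ROI, band) — a region has a single slow oscillation that can drive
several targets — which avoids the phase dilution that independent
per-edge rhythms would cause in hub layouts. All randomness flows from
the plan seed through `SeedSequence.spawn`, making cohorts
bit-reproducible.

Voxel clusters for the ROI-representation operations place one voxel
exactly at the coordinate centroid, scale the true source by an
exponentially distance-decaying gain, and add independent noise at the
stated snr; the first-principal-component representative beats the
centroid voxel at snr = 1 and matches it as snr → ∞.

**What the generator does not emulate:** field spread/volume conduction
(planted couplings are channel-local), realistic head geometry and lead
fields, sensor noise covariance, artifacts, non-stationarity across
epochs, and 1/f knees or oscillatory background peaks. Passing tests
therefore demonstrate correctness of the estimators, filters, and the
leakage-safe classification machinery on known ground truth — not
performance on real recordings, where source leakage and inter-subject
anatomy dominate the error budget.

## Problem sizes and numerical choices

Tests and the acceptance suite run at desk scale: N = 20 ROIs (the
layer/flattening code is exercised at N = 90 for shape checks),
25 + 25 subjects, 20 epochs × 4 s at fs = 250 Hz — with all bands
capped at 45 Hz, 250 Hz sampling is spectrally sufficient, and the
recovery experiments (planted 10-edge group difference → 5-fold
accuracy ≥ 0.9; permuted labels and null cohorts → chance) complete in
a few minutes on one CPU. Full-scale N = 90 / fs = 1000 runs are a
config change.

Other conventions: estimator epoch averages are arithmetic means;
PLV/iPLV pairwise matrices are computed per epoch as complex Gram
matrices of unit phasors; the analytic transform refuses near-constant
inputs (undefined phase); OMST refuses disconnected inputs, naming the
component sizes; comodulograms refuse empty selections; the PCA
representative's sign is fixed by positive correlation with the mean
voxel series, making results seed-independent.

## Known limitations

* The PAC noise floor (0.4) and FM excursion (60% of half-width) are
  generator conventions chosen once for a realistic
  detectable-but-not-saturated regime; they are not fitted to data.
* The max-symmetrization of directional CFC estimators inflates weights
  slightly relative to the mean convention (both are available).
* mRMR uses discretized MI with 8 quantile bins; with < ~20 training
  subjects per class the MI estimates are coarse, which is the realistic
  operating regime but makes single-fold rankings noisy — hence the
  cross-fold consensus report.
* LOOCV on small noisy cohorts exhibits the usual pessimistic bias;
  the 5-fold scheme is the primary metric.
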