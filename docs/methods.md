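# Methods

`coreact` analyses multi-session single-cell calcium recordings from
hippocampal CA1 in a retrospective memory-linking paradigm: a neutral
context is encoded first, an aversive context (with a weak or strong foot
shock) two days later, home-cage "offline" periods follow each encoding, and
the animal is later tested in the aversive, neutral and a novel context.
The package takes deconvolved event matrices and cross-session cell-match
tables as inputs and asks whether the ensembles encoding the two memories
co-reactivate offline, whether that co-reactivation is confined to
particular brain states, and whether it predicts ensemble reactivation
during recall. Because the in-vivo recordings are not publicly deposited,
the package ships a synthetic-experiment generator with planted ground
truth; every analysis stage is validated against that ground truth and
against independent brute-force implementations of its core statistics.

## Data model and alignment

An `EventMatrix` is a cells × frames array of nonnegative deconvolved event
amplitudes with per-frame wall-clock timestamps (ms) and a nominal rate
(30 frames/s; 15 frames/s for sessions paired with EEG/EMG). Frame indices
are 0-based and all intervals are half-open `[start, end)`. Cell identifiers
are per-session; identity across sessions exists only through match tables
(the output of a spatial-footprint cross-registration, consumed as-is and
validated for injectivity only — conflicting matches are taken at face
value).

Two alignment rules are shared by all stages:

* **Template alignment.** Behaviour recordings are aligned to an idealized
  constant-rate grid starting at the first timestamp; each slot takes the
  nearest recorded frame (ties to the earlier frame). A maximum displacement
  above 4 frame periods is logged as a warning.
* **Calcium-to-behaviour alignment.** Each behaviour frame takes the nearest
  calcium frame by wall-clock time, with no calcium frame serving more than
  two behaviour frames. When the cap binds, the two best-matching frames
  keep the overloaded calcium frame and the rest are greedily reassigned,
  worst first, to the nearest frame with remaining capacity. This greedy
  policy minimizes the worst-case residual misalignment; equidistant
  candidates resolve to the earlier frame so the map is deterministic.

Ensemble assignment partitions a session's cells into four groups from the
match tables: `neutral` (matched only to neutral encoding), `aversive`
(only to aversive encoding), `overlap` (both), `remaining` (neither).

## Burst detection and participation

Cells are z-scored along time (so no high-amplitude cell dominates;
zero-variance cells become zero rather than being dropped, which would
change ensemble denominators), averaged across cells, and the mean trace is
z-scored again. Maximal runs of frames with the trace strictly above z = 2
are burst events; the peak is the within-run argmax (earliest on ties). No
minimum duration and no run merging are applied. A cell participates in an
event if its own z-scored activity exceeds z = 2 on at least one frame of
the event; per-ensemble participation is the fraction of ensemble cells
participating, averaged over events.

**Shuffle control.** Each surrogate independently rotates every cell's event
train by a uniform circular shift, preserving per-cell rates and
autocorrelation while destroying across-cell synchrony, and reruns
detection. On sparse event data the doubly z-scored trace of an
*independent* matrix crosses z = 2 in roughly 2% of frames as many short
runs, whereas genuine synchrony concentrates the supra-threshold mass into
few long events and inflates the trace SD, suppressing incidental
crossings. Structured sessions therefore sit in the *lower* tail of the
null count distribution and the upper tail of mean event duration. The
package reports both one-sided empirical count p-values
(`(1 + #{null ≤ obs}) / (n + 1)` and the upper-tail analogue), a
mean-duration p-value, and a two-sided count p-value; "bursts are unlikely
under shuffled activity" is read as the observed configuration being
extreme against the null in either statistic.

**Peri-burst locomotion.** Locomotion is linearly interpolated onto a
regular grid centred on each burst peak (±5 s; grid step = the locomotion
sampling interval); events whose window leaves the recording are excluded.

## Co-participation and cross-correlations

Ensemble mean traces (per-cell z-score, within-ensemble mean, z-score
again) are computed for the neutral, aversive and overlap ensembles. An
ensemble participates in a burst if its mean trace exceeds z = 2 on any
frame of the event. An *independent* participation is an event in which
exactly one tracked ensemble participates; a *co-participation* for a pair
is an event in which both do (remaining cells are not tracked). The same
statistic over non-burst periods uses contiguous windows of length equal to
the session's median burst duration cut from the frames outside all events
(remainder of each gap dropped); an alternative frame-wise exceedance
statistic is available behind a config switch. For multi-session offline
designs, the per-session ensemble mean activities are concatenated in
temporal order, z-scored as one pseudocontinuous series, and burst events
are split at session boundaries so no event spans two recordings.

Time-lagged coupling: traces are cut into 120 s bins; within each bin the
Pearson correlation is computed at every integer lag up to ±5 frames
(~160 ms at 30 frames/s) on the overlapping samples, the signed maximum
over lags is kept, and the per-bin maxima are averaged (trailing partial
bin dropped, zero-variance bins skipped and counted).

## Reactivation and population vectors

* **Offline time course.** The offline matrix is z-scored along both axes
  (time per cell, then cells per frame), averaged across each ensemble's
  cells and within consecutive bins (default 60 s, exposed in config; the
  bin width is a display resolution, not a model choice). Note a property of
  this normalization on sparse event data: the per-cell time z-score forces
  every cell's mean to zero, and quiet frames — where the cross-cell spread
  is small — weight the (more negative) baseline of more active cells
  heavily, so a burst-reactivated ensemble's binned curve separates
  consistently *below* the remaining ensemble's. The separation, not its
  sign, carries the reactivation signal under this statistic, and the tests
  assert exactly that.
* **Recall reactivation.** Among cells active (≥ 1 event) in a recall
  session, the fractions previously active only in neutral encoding, only
  in aversive encoding, or in both are computed from the match tables. The
  reactivation index is the per-ensemble difference between neutral recall
  and novel exposure; positive values mean context-specific reactivation.
* **Encoding→recall similarity.** The encoding session's mean-activity
  vector over shared active cells is rank-correlated (Kendall's tau-b,
  tie-corrected because deconvolved mean vectors contain many zeros) with
  each 30 s recall bin's vector; the per-bin taus are averaged.
* **Encoding discriminability.** Shared active cells are binned at 30 s in
  both encoding sessions and the full bin × bin Pearson correlation matrix
  of the concatenation is computed; intra-session means exclude the
  diagonal, the inter-session mean covers the off-diagonal block.

## SVM decoding

Cells active in both encoding sessions form single-frame activity vectors
(the longer session trimmed from the end); a linear SVM (`LinearSVC`,
C = 1, per-cell z-scoring on by default with a config switch) is trained on
a random stratified half and scored on the held-out half, 50 times.
Controls: labels permuted independently per repeat, and a generator
configuration whose per-cell rates are identical in both contexts. The
chemotag variant restricts the cells to 20% bands of tagging-day
responsiveness (unranked cells last, ties by cell id) with a matched
shuffled control per band.

## Sleep scoring

EEG/EMG at 100 Hz is cut into 6 s epochs. Epoch band power is the mean
squared amplitude after a 4th-order zero-phase Butterworth band-pass
applied *per epoch* (filtering each epoch independently prevents power from
one state leaking into a neighbouring epoch of another state). EMG log
power is fit with a 2-component Gaussian mixture (lower component = sleep);
within sleep epochs the log theta/delta ratio (5–9 Hz over 0.5–4 Hz) is fit
with a second mixture (higher component = REM, lower = NREM). Mixtures are
initialized deterministically at the data extremes so a minority state
seeds its own component no matter how rare it is; fits whose component
means are closer than 0.2 log10 units fall back to all-wake (EMG stage) or
all-NREM (ratio stage) with a prominent warning. Epochs with more than 50%
missing samples are `unknown`. Because both stages operate on log power and
ratios, scoring is invariant to a global gain applied jointly to the
channels. Calcium frames take the state of the 6 s epoch containing them
(half-open intervals); frames outside all epochs are `unknown` and excluded
from state-specific statistics. Burst events take the state of their peak
frame for state-resolved co-participation.

## Chemotagging

The 45 min CNO session is analysed as continuous calcium traces. Each
cell's whole trace is min–max normalized to [0, 1] (normalizing the whole
trace, not the analysis window, so a cell whose transients fall outside the
window is not reduced to stretched noise); peaks with prominence ≥ 0.3 of
the normalized range and ≥ 2 s apart are counted within minutes 10–40.
Both thresholds are declared defaults of this package ("prominent" has no
standard quantitative definition) and are exposed in config. Cells are
ranked by count
(descending, ties by cell id) and the top 10% flagged as putative
inhibitory neurons, matching the expected inhibitory share of the CA1
pyramidal layer. Flags propagate to other sessions through match tables;
an unmatched cell counts as zero activity on tagging day and ranks after
every matched cell. Ensemble enrichment uses a one-sided hypergeometric
test of each ensemble against the whole population; the hypergeometric
choice is this package's, picked for exactness at small ensemble sizes.

## Synthetic experiments

The generator emulates the full paradigm with one latent cell registry per
animal; all match tables derive from shared latent identities (an optional
mismatch rate corrupts pairs, injectivity preserved, for bookkeeping
stress-tests). Defaults are chosen once as the study conditions; problem
sizes are scaled relative to the in-vivo recordings (150 cells, 600 s
offline sessions versus ~1 h in vivo) and every size and rate is a config
field.

* **Events.** Per-cell Bernoulli per frame (background 0.1 events/s) with
  log-normal amplitudes (σ = 0.5) — the simplest model of sparse
  deconvolved output.
* **Bursts.** 0.5 s windows at 3/min, ≥ 2 s apart, away from session edges.
  Ensemble participation follows a hub model: the overlap ensemble joins a
  burst with probability 0.9; given the overlap ensemble joins, the neutral
  and aversive ensembles join with the *coincidence* probabilities (0.8 /
  0.2 in the high-shock arm, 0.4 / 0.4 in the low-shock arm; 0.3 each
  otherwise), so the joint co-burst probability is the product. A cell of a
  participating ensemble engages with probability 0.8 and then fires
  Bernoulli(0.5) per window frame with at least one event guaranteed —
  sustained within-window firing is what separates bursts from the spiky
  background, and the guarantee gives exact closed forms for the
  participation expectations used as test oracles. Cells of tracked
  ensembles that do not participate receive no burst elevation; untracked
  (remaining) cells engage with probability 0.1. A per-state coincidence
  override plants state-specific co-bursting for EEG-paired designs.
* **Locomotion.** 10 Hz baseline 4 cm/s with Gaussian noise, multiplied by
  a Gaussian dip (depth 0.7, σ = 0.75 s) centred on each burst window.
* **Context patterns.** Cells shared between encodings are split evenly
  into neutral- and aversive-preferring; a cell fires at 2.0 events/s in
  its preferred context and 0.01 events/s otherwise (other cells 0.5
  events/s). This is the well-separated regime the in-vivo data show;
  setting both rates equal yields the label-independent control.
* **Recall composition.** Encoding-ensemble members reappear in each recall
  session with configured probabilities (overlap: 0.7 in neutral recall vs
  0.3 in novel under high shock; 0.35 / 0.35 under low shock); cells active
  in both encodings carry the overlap preference whether or not they were
  offline-active, since the recall analysis defines overlap by encoding
  membership. Recall rates are floored at 0.2 events/s so the planted
  composition is recovered exactly.
* **Sleep.** A semi-Markov hypnogram (mean bouts: wake 120 s, NREM 180 s,
  REM 60 s) drives EEG as state-amplitude-modulated 2.5 Hz and 7 Hz
  sinusoids plus broadband noise, and EMG as amplitude-modulated noise
  (wake 1.0; both sleep states 0.1, matching the scorer's two-state EMG
  assumption). With the noise SDs at zero the scorer recovers the
  hypnogram exactly.
* **Chemotag.** Continuous traces at 5 Hz: planted inhibitory cells
  (10% of the session, drawn with 4× weight on overlap-matched cells) emit
  ~1.5 transients/min within minutes 10–40; all cells emit background
  transients (at least one, so min–max normalization is never applied to
  pure noise) convolved with a 2 s decay kernel.

Generation is deterministic given (config, seed); each session draws from
its own seed stream, so dropping sessions from a config leaves the
remaining sessions bit-identical.

### What the generator does not emulate

No spatial footprints or registration errors beyond the optional mismatch
rate; no place fields or within-session drift; no calcium-indicator
kinetics in the event sessions (events are point amplitudes, not
transients); background rates are homogeneous within a session rather than
log-normally heterogeneous across cells; hypnograms have no artifacts or
micro-arousals. Passing tests therefore demonstrate that the analysis code
recovers the statistical structure it targets, not that real recordings
contain that structure.

## Problem sizes and numerical choices

Cohort studies default to 100 simulated animals per arm with 100-cell,
300–1200 s offline sessions, chosen so the full suite and the acceptance
script each run in minutes on one CPU; the acceptance checks state their
sizes explicitly. Empirical p-values use the add-one rule
`(1 + #extreme) / (n + 1)`. The SVM seed hierarchy derives per-stage seeds
from the master seed via SHA-256 so stages can be rerun in isolation.
Ties: burst peaks resolve to the earliest frame, chemotag ranks to the
lower cell id, alignment to the earlier frame.

## Known limitations

Single-frame SVM decoding degrades when few cells are shared between
encodings (many all-zero vectors); the optional frame binning mitigates
this. The non-burst windowing choice (median burst duration) is one of
several defensible readings of "non-burst periods"; the frame-wise variant
is provided for comparison. The sleep scorer assumes exactly two EMG
states and two theta/delta states; recordings violating that (e.g. all
wake) trigger the documented fallbacks. The offline-activity normalization
issue described above means its curves should be read as separation, not
ordering.
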