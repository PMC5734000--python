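# Methods

## Problem and model

`careflow` analyzes how care providers differ in the *clinical pathways* they
apply to stable ischemic-heart-disease patients. The pipeline works on a
time-stamped per-patient event table (`patient_id, day, zip, provider_id,
procedure, death`) with six procedures in three care categories:

| category | meaning | procedures |
|---|---|---|
| E | noninvasive, nonimaging | stress ECG |
| NI | noninvasive imaging | stress echocardiography, SPECT |
| I | invasive | coronary angiography (CA), PCI, CABG |

**Event series.** After phantom-event merging (same-procedure events within a
per-procedure window collapse into the earlier one; default: 2 days for SPECT
to absorb its two-day recording protocol, 0 for the rest), a patient's
timeline is split into *event series*: an event is an index event iff no
event of the patient occurred in the preceding `gap_days` (180) days *and*
its day is at least `gap_days` (the event-free prefix must be observable
inside the data window); the series runs to the next >180-day event-free
stretch, a death, or the end of observation. Same-day ties order E < NI < I,
then alphabetically by code, so classification is deterministic.

**Pathway types.** A series is labelled by the order of first occurrence of
its categories — exactly 15 possible labels (3 singles + 6 ordered pairs + 6
orderings of all three), in the fixed canonical order `E, E-NI, E-NI-I, E-I,
E-I-NI, NI, NI-E, NI-E-I, NI-I, NI-I-E, I, I-E, I-E-NI, I-NI, I-NI-E`.

**De facto centers.** Each ZIP area is assigned, per care level (primary=E,
secondary=NI, tertiary=I), the provider winning a majority vote in which each
resident patient with at least one event of the level casts one vote for the
provider of their first such event. Ties break to the lexicographically
smallest provider id (the choice is arbitrary but must be deterministic).
A patient's ZIP is their first event's ZIP; departments can be collapsed to
institutions through an explicit map. Series are attributed to the dominant
center of the patient's ZIP — spectra describe the population served, not the
performing provider.

**Spectra and outcomes.** A center's spectrum is its relative-frequency
15-vector over pathway types. Outcomes per scope: the *revascularization
rate* (share of CA-containing series with a PCI/CABG within 180 days of the
CA; linkage is by patient, so a follow-up landing in the next series still
counts; no CA anywhere → undefined, not 0), *365-day mortality* after the
index event, and the *average series cost* summed from the tariff table
(HUF per procedure; death events cost nothing). Direct standardization
(`direct_standardize`) re-weights stratum rates by a fixed reference
distribution when a stratification column is available.

## Correlation network

Centers are compared by Pearson correlation (`pearson_correlation`
implements the raw-sums form; a dual-route test checks it against the
covariance form to 1e-12) of their pathway profiles, and the complete graph
with weights `w_ij = c_ij + 2` (no cutoff; any offset ≤ 1 is rejected because
it could produce non-positive weights) is clustered.

**Why deviation profiles.** Applying the correlation to the *raw* 15 shares
is degenerate: every realistic center has roughly three quarters of its
series in the single-stress-test type, so any two raw spectra correlate near
+1 regardless of practice style, the weight matrix is almost uniform, and
modularity clustering collapses to one community. It also cannot produce the
correlation levels a center network is reported to show (intra-cluster
averages of ~0.1–0.4 and negative inter-cluster averages): those require the
shared component to be removed. The pipeline therefore standardizes each
pathway-type share across centers (z-score, zero-variance types dropped with
a log line) and correlates the resulting *practice-deviation profiles*; on
planted data this yields intra-cluster averages of ~+0.2–0.8 and negative
inter-cluster averages, the reported regime. `raw`, `center` (mean-removal
without rescaling) and `arcsine` (variance-stabilized) variants are exposed
via `profile_transform`. Fisher-z confidence bounds of the coefficients can
be computed (`correlation_confidence`) but never prune edges.

## Modularity and Louvain

Modularity is evaluated community-wise, `Q = Σ_c [Σin_c/2m − (Σtot_c/2m)²]`,
algebraically identical to the double-sum definition but exact for the
all-in-one partition (Q = 0.0 to the last bit, a conservation identity used
as a test). The Louvain optimizer is implemented natively: greedy local node
moves to the neighboring community with the largest positive ΔQ (ΔQ ties
break to the smallest community id; moves require a gain above 1e-12 to
avoid float cycling), followed by community aggregation (internal weight
moves onto self-loops counted in both directions so degrees are conserved),
repeated until aggregation changes nothing. `n_iterations` (default 10) caps
local-moving passes per aggregation level; `n_random_starts` (default 10)
restarts the whole procedure with seeds `seed … seed+9` and shuffled visit
orders, returning the highest-Q partition. On small complete
correlation-plus-offset graphs (the family this pipeline produces) the
optimizer matches exhaustive Bell-number enumeration of all set partitions;
on sparse random graphs greedy modularity optimization can genuinely miss
the global optimum (~3% of random ≤8-node Erdős–Rényi graphs, for this
implementation and networkx's alike) because merged communities can never
split — a known limitation of the method, not of this implementation.

Hierarchical clustering re-runs Louvain on each community's induced
subnetwork (weights retained; singletons pass through) to depth 3.
Centralities: weighted degree and shortest-path betweenness with edge length
`1/w` (strong correlation = short path; `unit` lengths available), with
percentile ranks on the whole network and per first-level cluster.

## Synthetic registry

The real register behind such analyses is administrative and not publicly
deposited, so the generator plants known structure and every distributional
choice is test scaffolding, not a claim about any real register:

* **Layout.** `n_centers` centers in contiguous archetype blocks; each ZIP
  maps to exactly one center (competition within a ZIP is out of scope, so
  ground truth stays unambiguous); patient volumes per ZIP are lognormal
  (`volume_sigma`, default 0.5; 0 = equal).
* **Archetypes.** Default archetype profiles are the three published cluster
  columns (renormalized — the printed percentages sum to 99.92–99.94).
  `spectrum_noise` (default 0.002) is a per-center deviation scale: center
  spectra are Dirichlet(archetype/noise) draws, giving ~1 percentage point of
  spread on a 5% share — a plausible practice-variation scale; 0 reproduces
  archetypes exactly.
* **Series realization.** Each patient gets one intended series (a second
  with probability 0.15, separated by >180 event-free days), its type drawn
  from the center's spectrum. Events appear in the label's category order
  with gaps of 1–`intra_series_gap_max` (60) days; the first I event is
  always a CA, and a PCI/CABG follow-up is appended with the archetype's
  revascularization probability (defaults 4.63/3.09/4.05%), which makes the
  revascularization statistic exercisable. Deaths are Bernoulli draws per
  pathway type (defaults from the published per-type 365-day mortality
  column; the one unreported type reuses its nearest sibling's value),
  placed after the last care event within 365 days of the index event.
  Construction guarantees that merging, index qualification and gap
  splitting return the intended series exactly, so labels round-trip.
* **Well-separated styles.** `separated_archetype_spectra()` provides three
  practice styles with pairwise profile correlation < 0.5 for recovery
  experiments (see below).

## What the simulation does and does not show

With the three *well-separated* styles, the full pipeline recovers the
planted center groups exactly (ARI 1.0 at 200 patients/center), the
recovered partition is invariant under the affine weight transform
`(c+2)·100` and stable (ARI ≥ 0.9) under `(c+2)²`, `(c+2)³` and `c+3`, and
an independent Louvain implementation (networkx) finds the same partition.

With the published *aggregate cluster profiles* as archetypes the three-way
structure is **not** recoverable at ~2,000 patients/center, and this is a
property of those printed profiles, not an implementation defect: with equal
group sizes the three deviation vectors sum to zero and the first two are
nearly anti-parallel (correlation ≈ −0.98), so the third profile is almost
exactly the midpoint of the other two on every well-measured pathway type;
its identity is carried by sub-percent types (I-NI, I-NI-E, E-I-NI) whose
expected per-center counts at that size are ~3–100 events. The
modularity-optimal partition then genuinely merges the two invasive-leaning
groups (2 clusters, ARI ≈ 0.42), under every profile transform tried (raw,
centered, z-score, log-ratio, arcsine). Recovery of all three groups from
these profiles requires roughly 16,000–20,000 patients per center. Real
center-level data can, of course, be better separated than the aggregates of
its clusters — aggregation averages away exactly the within-group practice
signature — so this bounds what the printed tables alone can support, not
what the method can do on source data.

The generator also does not emulate: repeat procedures inside a series
beyond the revascularization follow-up (so simulated series costs are lower
than published averages), cross-ZIP care seeking, provider competition
within a ZIP, demographic structure (an age column for standardization is
optional and off by default), or secular drift over the observation window.

## Numerical choices and degenerate inputs

* Percent differences use `100·(a−b)/b`; a zero reference is undefined
  (NaN, logged), matching the antisymmetry identity
  `(1+pd_ab/100)(1+pd_ba/100)=1`.
* Pairwise significance: two-sided Fisher exact tests on pooled 2×2 counts
  (type vs all other series; revascularized vs not among CA series; died vs
  survived); cost rows carry no test. p-values are validated against exact
  rational hypergeometric enumeration for all group sizes ≤ 12.
* Cluster summaries pool member centers' *counts* (not unweighted ratio
  means), so every whole-population value equals the n-weighted mean of the
  cluster values to float precision — the internal-consistency identity that
  also reproduces the published whole-population column from the printed
  cluster columns and n's.
* Empty centers are excluded from the network with a log line; constant
  profiles have undefined correlations and are likewise excluded; singleton
  clusters have undefined intra-cluster averages (NaN, flagged).
* Heat-map ordering sorts centers by (cluster, descending within-cluster
  average correlation, id), so it is invariant to input row order.
* All randomness flows from explicit integer seeds (`numpy.random.
  default_rng`); identical seeds give byte-identical registries and reports.

## Problem sizes

Default analysis runs use 30 centers and 60,000 patients (~2,000 per center,
emulation) or 6,000 patients (styles run); the optimality check uses 50
graphs of ≤ 8 nodes against full Bell-number enumeration; round-trip checks
use 10,000 patients. These sizes were chosen so every experiment is exact or
tightly concentrated while the whole suite stays quick to re-run.
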