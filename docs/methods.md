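# Methods

This note records the models, conventions and numerical choices behind
`routinemine`, in the spirit of a statistical package's methods appendix.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The routine model

A daily routine is a mapping

    dailyRoutine = { routine_period : period ∈ {night, morning, afternoon, evening} }

where each sub-routine is an ordered list of entries
`(activity, timespan, t_start, t_end, required, alt_group, category)`.
`timespan` is the mean duration of the activity's occurrences *within that
period* across the surviving days (repeats within a day are averaged
first when building clustering vectors, and pooled when building
entries); `t_start`/`t_end` are the earliest start and latest end observed,
so the entry's interval always contains its timespan. An activity can
appear in several periods with different statistics — an afternoon TV
session is a different routine object than an evening one.

Period windows are half-open minute ranges: night [00:00, 07:00),
morning [07:00, 12:00), afternoon [12:00, 19:00), evening [19:00, 24:00).
They are exhaustive: every time-of-day belongs to exactly one period.
A record is assigned by its **start** time and is not split when it
crosses a boundary (a 01:15–09:15 sleep is one night entry of 480 min);
splitting at boundaries is available behind a flag for users who prefer
per-period duration accounting. Midnight-spanning records belong to the
date they started. Timestamps are truncated to minute precision, so all
durations are integer minutes.

## Pattern mining

Support is document-based: the number of day-sequences containing at
least one gap-feasible embedding. This matches "how many days does the
behaviour repeat on" and is anti-monotone under extension, which the
pattern-growth search exploits for pruning. Closedness is defined through
the standard subsequence order: a frequent pattern is dropped exactly
when some frequent super-sequence has identical support. The miner grows
patterns over projected occurrence-position lists and closure is applied
as a post-filter; correctness is defined extensionally and is checked
against an independent brute-force enumeration oracle (exhaustive DFS
over index embeddings per sequence) on hundreds of random corpora in the
test suite.

The default gap constraint is [0, 0] — patterns are runs of strictly
consecutive activities — because consecutive-activity runs are the
robust core of an ADL schedule; the constraint is fully implemented and
exposed for users who want gapped patterns. Pattern length 1 is included:
a single reliably-repeated activity is informative for day filtering.
`min_support` has no universal value; the pipeline default of 5 days
(about a sixth of a month-long log) keeps activities present on ~50 % of
days frequent while excluding one-off events. Output order is canonical
(length, then lexicographic) so runs diff cleanly.

## Day filtering

Stage 1 keeps days containing at least one mined pattern, as a
contiguous substring of the period sequence, in ≥ 3 of 4 periods.
Containment is deliberately stricter than mining (no interspersed
activities, no permutations, even when mining used gaps): a candidate
routine day should exhibit the pattern literally. Stage 2 tabulates,
per period and over stage-1 survivors only, the distinct sequence
lengths; with `n` distinct lengths the acceptance threshold is
`(1/n)/2` of the period's sequences, and ties at the threshold pass.
A day needs ≥ 3 passing periods. The two stages compose: stage 2's
retained set is always a subset of stage 1's.

## Timespan vectors and collaborative clustering

All vectors of a period share one vocabulary (union of the period's
labels, ordered by first appearance), with zeros for absent activities,
so they are equal-length. DTW is still the assignment metric in K-Means
— it is tolerant of duration mass shifting between adjacent vocabulary
positions — but centroid updates are element-wise means: for
equal-length vectors the classical Lloyd step is well-defined and a DTW
barycentre is unnecessary. The k-means++ initialisation is seeded; 10
restarts keep the best objective; iteration stops when labels stabilise
or the assignment objective stops improving (the mean update is not the
exact DTW-optimal centre, so the explicit stop also guarantees
termination — the recorded objective history is non-increasing by
construction). Empty clusters are dropped rather than reseeded, so the
effective k can shrink on degenerate data.

Agglomerative clustering uses Manhattan distance with average linkage
(Ward would presuppose Euclidean geometry) through scipy's hierarchy
code, which also yields the dendrogram merge heights. On tied merge
heights (identical vectors) the flat cut collapses to fewer clusters;
callers see the actual cluster count.

Cluster-count selection scans k ∈ [2, n/2]: K-Means by maximum mean
silhouette with Davies-Bouldin as tie-break, the hierarchy by maximum
Dunn index with the same tie-break, smaller k preferred on exact ties.
Silhouette uses scikit-learn on a precomputed distance matrix (singleton
clusters score 0; fewer than two clusters scores 0 by convention).
Davies-Bouldin uses mean member-to-centroid scatter; Dunn uses minimum
pairwise inter-cluster distance over maximum intra-cluster diameter,
with `inf` for a zero-diameter but separated partition and 0 for
all-identical data.

The centroid-ratio filter checks each *performed* activity (zeros are
skipped; a performed activity against a zero centroid entry fails) —
durations below the centroid against `[centroid·(1−α), centroid]`,
durations above against `[centroid, centroid·(1+α)]`. Note the printed
source of this rule lists the "below" condition twice; the second branch
is implemented as ratio ≥ 1, the only reading that is reachable.
α defaults to 0.2 (a ±20 % duration corridor, wide enough to cover
ordinary day-to-day jitter, tight enough to flag halved/doubled
durations) and is configurable. The representative-cluster filter keeps
clusters of size ≥ max(2, ⌈0.10·N⌉).

A day passes a clustering route when **all** of its period vectors pass
that route's filter. The union combination is the default: the K-Means
route is systematically stricter (a day stranded near a foreign centroid
fails the ratio check even when its durations are ordinary), and union
recovers days that one algorithm alone would discard; intersection — the
literal reading of running both as a conjunctive filter — remains
available, and the pipeline reports both day sets either way.

## Routine assembly

Presence fractions over surviving days classify activities: ≥ 0.9
mandatory, ≥ 0.3 optional, below that excluded. The category names come
from the routine model; the cutoffs are package conventions (no
principled universal values exist) and are configurable. Alternative
("<>") detection is likewise a package rule: optional entries of one
period are grouped when their intervals overlap by ≥ 0.5 of the shorter
interval and they never co-occur in the same (day, period); groups are
connected components of that relation. Duration categories are
instant < 5 ≤ short < 30 ≤ medium < 120 ≤ long (minutes, right-closed
left buckets: exactly 30 min is medium).

Duration variants: when K-Means labels are supplied, an activity's days
are grouped by cluster and adjacent groups are merged while their mean
timespans differ by at most α times the smaller mean. Groups that remain
separate become distinct entries (e.g. an ~8 h and a ~10 h sleeping
variant); homogeneous activities collapse back to a single entry, so
over-fragmented clusterings do not leak into the routine.

Coverage over the full history counts a day when (a) some period
sequence contains a mined pattern contiguously, (b) at least half of the
day's activity *instances* carry labels occurring in frequent patterns
of their period (instances, not distinct labels, so a repeated anomalous
activity weighs accordingly), and (c) every instance whose label the
routine knows for that period matches some entry of that label:
duration within `timespan·(1 ± α)` and interval overlapping the entry's
interval. Activities the routine does not know are ignored — the routine
tolerates interleaved extras by design.

## Synthetic data

The generator is the package's test bed and ships as first-class code.
A template lists per-period activity specs (label, nominal start, mean
duration, duration/start jitter SDs, presence probability, alternative
group) plus a day count, noise-day share and seed. Per clean day:
mandatory activities always emitted, optional ones Bernoulli-included,
exactly one member per alternative group chosen uniformly, starts and
durations jittered with truncated normals (≥ 1 min), overlaps resolved
by forward-shifting (sequential ADL execution preserves order). Noise
days replace the schedule with a random sequence of vocabulary
activities at uniform-random durations (10–180 min) — far outside any
α-corridor, which is what makes them detectable. The noise share is
realised as a fixed count `round(p·n_days)` at random positions so the
planted contamination is exact for every seed.

The default template is a realistic month of a single person: night
toileting + ~8 h sleep, morning hygiene and breakfast with a mutually
exclusive late-morning toileting-or-TV slot, lunch / optional nap /
afternoon TV, dinner, evening TV and an optional snack. Duration jitter
SDs are 2–4 % of each mean — ordinary human variability, and far inside
the default α = 0.2 corridor, so clean days are not rejected as
anomalous. What the generator does *not* emulate: activity-recognition
errors, missing records, weekday/weekend structure, seasonal drift, or
multi-resident confusion. Passing tests therefore demonstrate the
mining/clustering/assembly machinery, not robustness to upstream
classifier noise.

Problem sizes used by the tests and the acceptance script — 30-day logs,
200 random mining corpora (alphabet 5, length ≤ 8, ≤ 10 sequences),
500-day statistical-fidelity checks — are chosen so the whole suite runs
in about a minute on one CPU while still exercising every stage at a
scale where the planted structure is unambiguous.

## Known limitations

* DTW on vocabulary-ordered duration vectors treats the vocabulary order
  as a pseudo-time axis; with small vocabularies it behaves close to
  Manhattan distance. It is kept as the assignment metric for fidelity
  to the routine model's design.
* The K-Means route's centroid-ratio filter is harsh on optional *short*
  activities when cluster structure does not separate
  presence/absence — the centroid then averages zeros and present days
  fail the ratio check. The union combination compensates; this is the
  concrete reason union coverage dominates intersection.
* Holdout evaluation splits chronologically by default (a routine should
  generalise forward in time); a seeded random split is available. The
  pipeline reports coverage on the train and holdout portions separately
  and on the full history.
* Coverage condition (b) counts instances; a day consisting of many
  repetitions of a single frequent activity can pass (b) while still
  failing the timespan conditions.
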