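# Methods

This note documents the models and algorithms implemented in `burstlab`,
the parameter defaults and why they are what they are, the numerical
choices made where a published description leaves room, and the limits of
what the synthetic benchmark can show about real recordings.

## Conventions

Time is in seconds everywhere, including on-disk formats (published
parameter tables mix seconds and milliseconds; a single unit avoids
conversion drift). Spike indices are 0-based; burst index ranges are
inclusive at both ends; burst time intervals are closed
`[begin_time, end_time]`, taken as the first and last spike times of the
burst. Every detector enforces a global floor of three spikes per burst —
the conventional minimum for calling a spike pattern a burst — and
detectors given fewer than three spikes return an empty `BurstSet` rather
than an error. A burst may begin at the first and end at the last spike of
a train. Duplicate spike times are rejected at read time, since the
rank-based methods require strictly positive ISIs.

## Detectors

### MaxInterval (`mi`)

Bursts are seeded at any ISI ≤ *max begin ISI* (default 0.17 s), extended
while ISIs stay ≤ *max end ISI* (0.3 s), merged with the next burst when
the gap is < *min interburst interval* (0.2 s; the sequential left-to-right
merge is iterated to a fixpoint, so chains of close bursts collapse), and
finally filtered by *min duration* (0.01 s) and *min spikes* (3). Because
all five thresholds are absolute, the same parameter set applies to every
electrode of a recording. Defaults follow the NeuroExplorer manual's
suggested values.

### Poisson surprise (`ps`)

The null is a homogeneous Poisson process at the train's mean firing rate
λ = n/duration. For an interval of length `T` containing `N` spikes,

    S = −log P(Poisson(λT) ≥ N).

The upper tail is summed term-by-term in log space (`logsumexp` over
`k log μ − μ − log k!`), which stays exact where a linear-domain survival
function underflows; surprise values of several hundred are representable.
Burst search follows the classic surprise-maximization scheme: seed on
runs of ≥ 2 consecutive ISIs shorter than half the mean ISI, extend the
burst end forward choosing the best of up to 10 spikes at a time
(`lookahead`, configurable) while S grows, trim leading spikes while that
increases S, then apply single-step moves at both ends until no one-spike
extension or trim improves S. Bursts with `S ≥ −log(0.01)` are kept, in
scan order, without overlap.

### Rank surprise (`rs`)

ISIs are ranked over the whole train, smallest first, with mid-ranks for
ties (mid-ranks preserve the rank-sum null under ties). Candidate windows
are sub-runs of ≥ 2 consecutive ISIs at or below the 75th-percentile ISI.
The statistic is `RS = −log P(Σ ranks ≤ observed)` where the null is a sum
of `q` i.i.d. uniforms on `{1..N}`. The exact distribution is built by
iterated sliding-window convolution and cached per `(q, N)`; above
`exact_limit = 60` ISIs a continuity-corrected Gaussian (mean `q(N+1)/2`,
variance `q(N²−1)/12`) evaluated through `norm.logcdf` takes over. All
windows are scored exhaustively, then accepted greedily by descending RS
(ties to the earlier start) with overlap exclusion; a one-ISI halo keeps
accepted bursts from sharing a boundary spike.

### Robust Gaussian surprise (`rgs`)

Log-ISIs from all supplied trains are pooled; the central distribution has
center = median and spread = MAD × 1.4826 (Gaussian-consistent, so the
−2.58 multiplier reads as a two-sided 1% normal tail; the scaling is
configurable via `gaussian_consistent_mad`). ISIs whose normalized log
value falls below −2.58 spreads seed candidate bursts; seeds are extended
by single-step moves at either end while the burst surprise

    GS_B = −log Φ( Σ xᵢ / (σ√k) )

grows (the lower tail of a sum of k central-distribution Gaussians), and
bursts below `−log(0.01)` are discarded. Degenerate pooled distributions
(zero spread) yield no bursts. When several trains are supplied the
central distribution is shared — duplicating a train therefore cannot
change the result, which is verified by test.

### ISI rank threshold (`irt`)

θ_C is the smallest integer count whose upper-tail frequency over disjoint
1-s windows is ≤ 0.05 (the truncated final window contributes its raw
count; the tail reading of "P(C) = 0.05" is used since a cutoff needs a
tail). Each spike's forward count is the number of spikes in the following
1 s (excluding itself), and its rank value is the normalized mid-rank of
the following ISI. A burst opens at a spike with forward count > θ_C and
rank < 0.5 and closes at the first subsequent spike whose forward count
drops below θ_C/2.

### Cumulative moving average (`cma`)

The ISI histogram uses 1-ms linear bins (configurable; the original leaves
the width open). `CMA[i]` is the running mean of the counts of bins
`0..i`; the curve rises to a peak and decays roughly hyperbolically. The
skewness of the *distribution of CMA values* selects `α₁` (1.0 / 0.7 /
0.5 / 0.3 for skew < 1 / < 4 / < 9 / ≥ 9). The sample-skewness reading is
deliberate: weighting bins by their ISI value instead yields small skews
and degenerate few-ms cutoffs on strongly bursting trains, contradicting
the method's published behavior. The cutoff bin is the one at or beyond
the CMA peak where the CMA is closest to `α₁·CMA_MAX` (the rising flank is
excluded for the same reason), and bursts are runs of > 2 spikes with ISIs
below that cutoff. Only burst cores are reported; the original
burst-related-spike extension driven by `α₂` is intentionally omitted.

### logISI (`logisi`)

The histogram of log₁₀(ISI) uses 10 bins per decade, smoothed with a
1-bin-σ Gaussian kernel before peak finding (the original defers to a
bespoke peak finder; bins and smoothing are exposed in `LogIsiParams`).
Peaks are local maxima of the smoothed histogram, with zero padding so
boundary bins can qualify. The intraburst peak is the tallest peak at an
ISI ≤ `max_cutoff` (100 ms); without one, no bursts are reported. For each
later peak the minimum between it and the intraburst peak is scored with
the void parameter `v = 1 − h_min/√(h_peak1·h_peak2)`, and the first
minimum with `v ≥ 0.7` fixes `maxISI`. If `maxISI ≤ max_cutoff`, bursts
are runs of ≥ 3 spikes with ISIs < `maxISI`. If the selected cutoff
exceeds the cap — or none clears the void threshold — cores are detected
at the 100-ms cap; when a larger cutoff exists, core edges are extended to
absorb neighboring spikes whose adjoining ISIs are below it, merging
bursts that meet.

## The simulator

The generators reproduce the benchmark train families (properties D4–D11),
each 300 s by default, 100 trains per property:

| property | model | parameters |
|----------|-------|------------|
| D4 | Poisson | λ = 1 Hz |
| D5 | Poisson / gamma renewal (half each) | λ = 0.5 Hz; shape 1, rate 0.5/s |
| D6 | inhomogeneous Poisson | λ(t) = 1 + t/300 Hz |
| D7 | Poisson bursting | λ = 0.2 Hz, n = 5, r = 0.3 s |
| D8 | nonstationary bursting | λ = 0.3 Hz, n ~ U(5,18), r ~ U(0.3,3) s |
| D9 | Poisson bursting | λ = 0.1 Hz, n = 18, r = 3 s |
| D10 | Poisson bursting | λ = 1 Hz, n = 10, r = 0.5 s |
| D11 | noisy bursting | λ = 0.5 Hz, n = 8, r = 0.8 s; noise shape 1, rate 0.5/s |

Nonbursting trains (D4–D6) have the smallest 10% of ISIs removed — for
each selected ISI the later bounding spike is deleted — to strip chance
burst-like runs; their ground-truth burst sets are empty by construction.

In the Poisson bursting model, burst centers form a Poisson process of
rate λ; each burst's spike count is Poisson(n), resampled until ≥ 3
(smaller "bursts" would be undetectable under the global three-spike floor
and would poison true-positive accounting; `min_spikes` exposes the knob);
spike positions are uniform on a width-r window centered on the burst,
sorted, with exact ties resampled. A burst whose spikes would leave
[0, duration] is discarded, not clipped. Overlap between bursts is
resolved in center order: a burst whose occupied interval
[first spike, last spike] intersects an earlier kept burst's interval is
dropped whole. In the nonstationary variant, per-burst n and r are uniform
draws and only bursts with within-burst rate (spike count over occupied
duration) above 5 Hz are retained; zero-duration bursts pass, their rate
being unbounded.

The noisy variant superposes an independent gamma-renewal noise train
(shape 1, rate 0.5/s, smallest 10% of ISIs trimmed) on the bursting
train. Noise spikes are removed inside a ±0.5-s exclusion zone around each
kept burst's *center* (and inside the burst span itself). At the default
spread of 0.8 s the zone covers the whole burst window plus a protective
strip, so burst and noise spikes never overlap. Referencing the zone to
the center rather than the span edges is deliberate: it is the reading
under which the model's ground-truth composition matches its published
mean of 91% of spikes in bursts (the span-referenced reading stabilizes
near 93.5%, incompatible with that figure); parameters are identical
either way. With 100 trains the composition lands at 91.4–91.6% across
seeds.

Seeding is hierarchical: `simulate_property(prop, i, seed)` builds an
independent substream from `(seed, property number, train index)`, so any
single train of a benchmark run can be regenerated in isolation and
distinct indices give independent trains. All generators accept either an
integer seed or a `numpy.random.Generator`.

What the simulator does **not** emulate: refractory periods, bursts with
internal rate structure (accelerando/decelerando), firing-rate
correlations across electrodes, network-wide bursts, electrode noise and
spike-sorting artifacts. Passing benchmarks on these trains therefore
shows that a detector recovers bursts under the stated point-process
assumptions, not that it is optimal on any particular biological
preparation.

## Evaluation

True/false-positive spike fractions compare detected membership with
ground truth: TP = detected burst spikes / all burst spikes, FP = detected
noise spikes / all noise spikes; an empty denominator yields NaN, never a
defined-by-fiat zero. Sensitivity and false-positive rate against
annotated (interval-based) bursts use interval membership on both sides.
ROC sweeps vary one parameter per method — the probability cutoff for the
surprise methods, the count-cutoff tail level for IRT, the cutoff cap for
logISI, the beginning ISI for MaxInterval with the end ISI held 0.130 s
above it — and score by Euclidean distance to the perfect corner (0, 1),
since structural limits (e.g. the three-spike floor) keep the curves from
spanning the full range; CMA contributes a single operating point.
Averaging across trains is per-train by default, with pooled-spike
averaging available. Burst masks binarize bursting state over 50-ms bins
(configurable) and are compared by normalized Hamming distance. The
interburst interval is end-to-next-start (onset-to-onset is exposed as an
option); its coefficient of variation needs at least two IBIs and is NaN
below three bursts. A detected burst "recovers" a ground-truth burst when
their time intervals intersect; no one-to-one correspondence is enforced
for the burst-count ratio.

`run_property_benchmark` evaluates every detector per train and returns a
tidy (train, method, metric, value) table; summaries report median and
IQR, matching the box-plot statistics conventional for this benchmark.
The RGS method pools ISIs per call as it would across electrodes of one
recording; in the benchmark each simulated train is an independent
recording, so pooling is per train.

## Presets

Two parameter regimes ship: `default` (the synthetic-benchmark values
above) and `hipsc`, the regime used for human iPSC-derived network
recordings — Poisson surprise threshold `−log(0.0025) ≈ 6`, MaxInterval
beginning ISI 0.2 s, logISI cap 150 ms.

## Problem sizes

The test suite and the acceptance script run the benchmark at its
published scale — 100 trains of 300 s per property — which completes in
seconds; nothing is scaled down.

## Known limitations

* The surprise-maximization search (PS) is a local hill climb; it
  guarantees local maximality (no single-spike move improves S) but not
  the global optimum over all interval sets.
* The rank-surprise exhaustive search is quadratic in the length of each
  admissible ISI run; pathological trains consisting of one long
  uniform-ISI run are slow (the 75th-percentile limit keeps realistic
  runs short).
* The hidden semi-Markov model detector is not implemented (its reference
  implementation carries 23 coupled parameters and an MCMC sampler); the
  plugin hook accepts an external wrapper.
* CMA burst-related-spike extension is intentionally omitted (core
  detection only).
* Annotated burst boundaries read from CSV are treated as exact; no
  boundary tolerance is applied.
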