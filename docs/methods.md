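# Methods

This note documents the models, estimators and numerical choices behind
`dielrhythm`, and what the synthetic-data generator does and does not
emulate.

## Behavioral rhythm analysis

**Binning and normalization.** Tracked displacement events are summed into
hourly bins (`[h, h+1)` labeled by bin start). Each animal's series is
rescaled to percent of its own maximum hour; this makes cohort averages
invariant to per-animal scale (body size, metabolic rate) but ties the
scale to a single extreme bin, so normalized means are mildly biased
downward when noise is large relative to the peak (the max of a noisy
series exceeds the max of its expectation). Animals that never move cannot
be normalized and are excluded with a log message. Cohort means use the
n−1 sample SD for standard errors; a single animal reports SE 0.

**Periodogram.** Sub-hour period resolution from hourly data is obtained
by evaluating power on a dense period grid (default 16–32 h, step 0.01 h).
Power at trial period T is the explained sum of squares of the two-regressor
harmonic least-squares fit (cosine + sine at frequency 1/T, with the
classical tau rotation that makes the regressors orthogonal). This is the
Lomb–Scargle periodogram up to a factor 2 and coincides with two-sided DFT
power (scaled 2/N) on the natural Fourier grid, where Parseval holds: the
one-sided natural-grid powers sum to N × variance. The raw squared DFT sum
was rejected for off-grid evaluation because the interference cross-term
between the ±f Dirichlet kernels biases the argmax of even a noiseless
24-h cosine by up to ~0.4 h, with the sign depending on phase; the
least-squares power is exact at a pure tone's period by construction
(perfect fit ⇒ maximal explained SS). Series are mean-centered first so
the DC term never competes. Dominant period is the grid argmax, first
index on ties; a constant series is flagged degenerate.

**Significance.** The study literature rarely states the test behind "a
single significant periodogram peak", so a distribution-free max-power
permutation test is used: hourly bins are shuffled (destroying temporal
order, preserving the marginal distribution), the maximum grid power is
recomputed, and p = (1 + #{null max ≥ observed}) / (1 + N_perm), exact
under exchangeability. Default 1000 permutations, α = 0.05. A constant
series returns p = 1.

**Day/night summaries and phase shifts.** Per-animal totals are split by
the light state at each bin start and divided by the number of recorded
days, giving per-12-h-phase totals comparable across recording lengths.
Daily peaks are the argmax of the cohort mean within each 24-h window
after a 3-h centered moving average (edges truncated); smoothing is needed
because single daily peaks are called on visibly noisy means. Phase shifts
are circular differences baseline − peak mapped to (−12, 12], positive =
advance. ZT0 = lights-on; all peaks are reported in [0, 24).

## Expression analysis

**Filtering.** Read records keep unique alignments with ≤ 2 mismatches,
then one record per (gene, strand, start) — identical start positions are
treated as PCR duplicates. The operation is idempotent and order-stable
(first occurrence wins).

**Normalization.** The pseudo-reference is the per-gene geometric mean
across samples over genes positive in every sample (no time point is
privileged as reference). Per sample, M_g = log2(x_gs/ref_g); values below
the 25th or above the 75th percentile of M are trimmed; survivors are
averaged with weights 1/sd_g, sd_g = sqrt(1/x_gs + 1/ref_g) (delta-method
SD of a log count under Poisson noise; the ln 2 factor cancels in the
weighted mean). log2 c_s is that weighted mean, so the defining identity —
trimmed weighted mean of (M_g − log2 c_s) = 0 — holds to rounding. Factors
are identified only up to one global constant (scaling all libraries
equally is unobservable); tests align recovered and true factors by their
geometric means before comparing. Genes with zeros stay in the normalized
matrix via a 0.5 pseudocount but never enter factor estimation. Fewer than
8 usable genes raises an error rather than returning unstable factors.

**Replicate concordance.** Conditional on a gene's total n = x1 + x2, x1
under the Poisson null is Binomial(n, N1/(N1+N2)) with N the library
totals. The 99% region is equal-tailed (0.005 per side) via binomial
quantiles; discreteness makes coverage ≥ 99%, so the concordant fraction
under the null sits slightly above 0.99. Genes with n = 0 carry no
information and are skipped; genes with tiny totals have regions covering
everything and count as concordant, which is the honest reading of "within
expected Poisson noise".

**g-factor.** Series are mean-centered; powers are |rfft|² on the natural
grid; g = P(1/24 h) / Σ_{f>0} P(f) with the sum over positive frequencies
up to Nyquist. Excluding DC is deliberate: with DC included the score
would depend on expression level, contradicting its use as a rhythmicity
score (g is invariant to additive offsets and positive scalings). The
harmonics variant adds P at on-grid multiples of the 24-h frequency (12 h,
8 h for a 12-point 4-h series), scoring non-sinusoidal waveforms; a square
wave scores g_harmonic = 1 exactly. The target period must lie on the
natural grid (24 h is bin 2 of a 12 × 4-h series); off-grid requests raise
rather than silently interpolating. Rhythm scoring uses the normalized
log2 matrix (replicate columns averaged after normalization, before
scoring); raw counts can be scored by passing them directly. DCG selection
is strict: g > cutoff (default 0.5).

**Clustering and peak phase.** Profiles are z-scored per gene so only
temporal shape matters; K-means (Euclidean, K = 5, 50 seeded restarts,
best within-cluster SS) assigns clusters, which are relabeled 1..K by
ascending circular-mean peak ZT of their members so labels follow the diel
cycle. Peak ZT is the phase of the 24-h DFT coefficient mapped so that a
cosine peaking at ZT p returns exactly p; a degenerate (zero-power)
profile reports a missing peak.

## Comparative filter

The day/night fold filter on homolog count pairs is inclusive
(day ≥ 3 × night passes at exactly 3-fold — required for printed pairs like
9/3 to qualify) and operates on raw counts, matching how such printed
tables are screened; no statistical test is attached because the source
counts carry none. A zero opposite count with a positive count is an
infinite fold and passes. If both directions qualify simultaneously
(possible only at thresholds ≤ 1 with near-equal counts) the pair is
classed as no difference, keeping the filter exactly symmetric under
swapping day and night. Homology itself is taken as given via mapping
tables; the two packaged tables are transcriptions of published homolog
lists used as fixtures.

## Synthetic-data generator

The generator defines the study conditions for every test. Activity:
hourly activity = scale_a × (baseline + amplitude × w(t)) + N(0, noise_sd),
clipped at 0, with w a raised cosine in [0, 1] peaking at ZT18 (mid-dark).
Defaults — baseline 4.5 cm/h, amplitude 13.5 cm/h, noise 2 cm/h, scales
uniform in [0.5, 2] — were chosen so the expected per-phase totals of an
LD cohort (~188 cm dark vs ~84 cm light per 12 h) match the magnitudes
reported for adult anemones; the waveform is smooth so the analytic
g-factor and periodogram limits are exact (a square-wave option exists via
the harmonics variant's tests). Condition semantics: LD and DD keep the
entrained rhythm (DD models a free run continuing at the entrained
period); LL and `arrhythmic` zero the rhythmic term; a dark pulse advances
the phase by a configurable offset (default 2 h) from the pulse hour
onward; a light pulse zeroes the rhythmic term from the pulse onward.
These are phenomenological summaries of observed pulse responses, not an
entrainment-dynamics model. Clipping at zero slightly biases means upward
at low activity; inter-animal heterogeneity as uniform scale multipliers
is a modeling choice, not inferred from data. Randomness: one
`SeedSequence` per cohort, per-animal substreams spawned deterministically
— identical spec + seed is bit-identical.

Expression: counts ~ Poisson(c_s · μ_g · m_g(t)) with log2 μ_g ~
N(5, 1.5²) (typical depth ~32 counts), rhythmic genes modulated by
2^(A cos(2π(ZT − φ)/24)) with A = 1 (4-fold peak-to-trough) and φ drawn
from the phase set (default six 4-h-spaced phases starting ZT1; screens of
five planted groups pass a five-phase set). Sampling starts at ZT1 (the 8
am draw of a 7 am lights-on design) every 4 h for 12 points over two days.

What passing tests do **not** show about real data: the generator has no
read-level structure (no mapping bias, no overdispersion beyond Poisson,
no gene-length effects), hourly rather than frame-level tracking, no
entrainment transients after pulses, and no inter-gene correlation.
Results on real libraries (e.g. the published 180-gene DCG count or the
96% replicate concordance) depend on those properties and on the actual
accession, and are deliberately not asserted anywhere.

## Problem sizes and tolerances

Simulation-backed tests use the study's design points where stated (35 LD
/ 20 DD animals, 72 h; 5000 genes with 180 planted rhythmic; 12 × 4-h
libraries) and otherwise the smallest cohorts that leave the checked
statistic well-resolved (e.g. 10-animal LL replicates, 200-permutation
tests at a 0.05 level, a 0.05-h grid for replicated calibration runs).
Exact identities are asserted at 1e-9; statistical checks state their
replicate counts and use fixed seeds. Multi-comparison checks (72 hourly
bins against a Monte-Carlo reference) allow the expected number of 3-SE
exceedances rather than demanding a simultaneous band.
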