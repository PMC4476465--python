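# dielrhythm

Circadian rhythm analysis for cnidarian time-course studies: behavioral
locomotor-rhythm detection and diel transcriptome profiling, with a seeded
synthetic-data generator so the whole pipeline can be exercised and
validated without any external download.

The package targets the classic experimental designs used to characterize
the clock of the sea anemone *Nematostella vectensis* and related corals:
animals tracked for ~72 h under 12:12 light:dark cycles (LD), constant dark
(DD), constant light (LL) and 1-h dark/light pulses; and RNA-seq libraries
sampled every 4 h over two consecutive days.

## What it computes

**Behavior.** Per-animal displacement is summed into hourly bins and
expressed as a percentage of that animal's maximum hour (removing body-size
and metabolic differences), then averaged over the cohort with standard
errors. The period of the averaged rhythm is read from a dense-grid
periodogram: at each trial period *T* (default 16–32 h, step 0.01 h) the
power is the explained sum of squares of the harmonic least-squares fit at
frequency 1/*T* — the classical Lomb–Scargle periodogram, equal to DFT
power on the natural Fourier grid, but with an argmax that is exact for a
pure tone even between grid points. Significance of the dominant peak comes
from a max-power permutation test over shuffled hourly bins:
*p* = (1 + #{permuted max ≥ observed max}) / (1 + *N*<sub>perm</sub>).
Daily activity peaks (after 3-h smoothing) and circular phase shifts in
(−12, 12] h quantify pulse experiments; positive shifts are advances.

**Expression.** Aligned-read records are filtered (unique alignment, ≤ 2
mismatches) and de-duplicated by start position, tallied into a gene ×
time-point count matrix, and normalized with a trimmed-mean-of-log-folds
scheme: per-sample log2 fold changes *M*<sub>g</sub> against a geometric-mean
pseudo-reference are quartile-trimmed and averaged with inverse Poisson-SD
weights *w*<sub>g</sub> = 1/√(1/x<sub>gs</sub> + 1/ref<sub>g</sub>), giving size
factors *c*<sub>s</sub> with the defining property that the trimmed weighted
mean of *M*<sub>g</sub> − log2 *c*<sub>s</sub> vanishes. Rhythmicity of each
gene is scored by the **g-factor** — the ratio of periodogram power at the
24-h frequency to total power over all positive frequencies (DC excluded;
optionally adding the 12-h, 8-h, … harmonics to the numerator) — with
g > 0.5 selecting diel cycle genes (DCGs). DCGs are clustered into K = 5
phase groups by seeded K-means on z-scored profiles, and each gene's peak
Zeitgeber time is the phase of its 24-h Fourier component. A replicate
concordance check asks, per gene, whether one library's count falls in the
central 99% region of the depth-conditional binomial — the fraction is
~0.99 for true Poisson replicates.

**Comparative.** Homolog tables against coral day/night data are joined to
the DCG set, and printed day/night count pairs are split by an inclusive
≥ 3-fold filter (a zero opposite count counts as infinite fold).

**Synthetic data.** `ActivitySimSpec`/`ExpressionSimSpec` generate cohorts
and count matrices with known ground truth: nocturnal raised-cosine
activity (peak ZT18) with uniform per-animal scale multipliers, Gaussian
noise, and LD/DD/LL/pulse/arrhythmic condition semantics; Poisson counts
with planted cosine-modulated rhythmic genes in chosen phase groups and
per-library size factors. Identical spec + seed gives bit-identical output.

## Worked example

```sh
python examples/locomotor_rhythm.py
```

```
LD (n=35): dominant period  24.04 h, permutation p = 0.0010 (rhythmic)
DD (n=20): dominant period  24.04 h, permutation p = 0.0010 (rhythmic)
LL (n=30): dominant period  26.55 h, permutation p = 0.7742 (not rhythmic)
LD dark total 227.0 cm (SE 13.8) vs light total 101.7 cm (SE 6.2), n=35
```

The entrained (LD) and free-running (DD) cohorts show a dominant period at
~24 h with a permutation p-value at the resolution floor of 1000
permutations — a circadian rhythm that persists without the light cue —
while the constant-light cohort's nominal peak is noise (p ≫ 0.05). The
day/night totals show the nocturnal bias: animals cover more than twice the
distance during the dark phase. The other scripts in `examples/` walk
through pulse-induced phase shifts, the g-factor screen with K-means phase
clusters, replicate concordance, the homolog fold-change filter, and the
end-to-end pipeline with its reproducibility manifest (also available as a
CLI: `dielrhythm all --seed 7 --out runs/demo`).

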