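"""Diel transcriptome profiling from gene x time-point read counts.

Implements the RNA-seq arm: filtering/de-duplication of aligned-read
records, a trimmed-mean-of-log-folds (TMM-style) normalization with inverse
Poisson-SD weights, a Poisson replicate-concordance check, the g-factor
rhythmicity screen on the natural FFT grid, selection of diel cycle genes
(DCGs), K-means phase clustering, and peak Zeitgeber-time estimation from the
phase of the 24-h Fourier component.

The g-factor of a series is the ratio of the periodogram power at the 24-h
frequency to the summed power over all positive frequencies up to Nyquist
(DC removed by mean-centering, so the score is invariant to expression
level); values near 1 indicate a nearly pure 24-h rhythm. A variant adds the
on-grid harmonics of 24 h (12 h, 8 h, ...) to the numerator to score
non-sinusoidal waveforms.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ReadRecord",
    "SizeFactors",
    "GFactorTable",
    "ClusterResult",
    "NormalizationError",
    "filter_and_dedup",
    "tally_counts",
    "poisson_tmm_normalize",
    "replicate_concordance",
    "g_factor",
    "g_factor_table",
    "select_dcgs",
    "kmeans_phase_clusters",
    "estimate_peak_zt",
    "collapse_replicates",
    "parse_sample_label",
    "sample_zt_hours",
]


class NormalizationError(ValueError):
    """Raised when too few genes are usable for size-factor estimation."""


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: gene, 0-based start, strand, mismatches, uniqueness."""

    gene_id: str
    start: int
    strand: str
    mismatches: int
    uniquely_aligned: bool

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class SizeFactors:
    """Per-sample scaling constants c_s with the per-gene detail behind them.

    ``detail[sample]`` is a DataFrame (indexed by the genes used) with the
    log2-fold change ``M`` against the pseudo-reference, the inverse-SD
    weight ``w``, and a ``trimmed`` flag marking values dropped from the
    upper/lower quartiles of M.
    """

    factors: pd.Series
    detail: dict[str, pd.DataFrame]
    n_genes_used: int


@dataclass
class GFactorTable:
    """Per-gene rhythmicity scores (fundamental-only and with harmonics)."""

    table: pd.DataFrame  # columns: g, g_harmonic, degenerate
    harmonics_included: bool = True


@dataclass
class ClusterResult:
    """K-means phase clusters of DCG profiles.

    Cluster labels are 1..K ordered by ascending circular-mean peak ZT of
    the member genes; ``empty`` lists labels with no members after
    convergence (degenerate inputs).
    """

    assignment: pd.Series
    k: int
    seed: int
    restarts: int
    cluster_profiles: pd.DataFrame
    cluster_peak_zt: pd.Series
    empty: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read-record filtering and tallying


def filter_and_dedup(
    records: list[ReadRecord], max_mismatches: int = 2
) -> list[ReadRecord]:
    """Apply the unique-alignment / mismatch filter, then start-position dedup.

    Keeps records that aligned uniquely with at most ``max_mismatches``
    mismatches, then keeps the first record per ``(gene_id, strand, start)``
    — duplicate start positions are likely PCR artifacts. Idempotent.
    """
    seen: set[tuple[str, str, int]] = set()
    out: list[ReadRecord] = []
    for r in records:
        if not r.uniquely_aligned or r.mismatches > max_mismatches:
            continue
        key = (r.gene_id, r.strand, r.start)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def tally_counts(
    records: list[ReadRecord],
    gene_ids: list[str],
    sample_label: str,
    unknown_gene_log: list[str] | None = None,
) -> pd.Series:
    """Count surviving records per gene for one library.

    ``records`` must already be filtered/de-duplicated. Records for genes
    not in ``gene_ids`` are skipped and appended to ``unknown_gene_log``.
    """
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), name=sample_label)
    known = set(gene_ids)
    for r in records:
        if r.gene_id not in known:
            if unknown_gene_log is not None:
                unknown_gene_log.append(r.gene_id)
            continue
        counts[r.gene_id] += 1
    return counts


# ---------------------------------------------------------------------------
# normalization


def poisson_tmm_normalize(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    min_genes: int = 8,
) -> tuple[SizeFactors, pd.DataFrame]:
    """Poisson-weighted trimmed-mean-of-log-folds normalization.

    For each sample s, log2-fold changes ``M_g = log2(x_gs / ref_g)`` are
    computed against a pseudo-reference (the per-gene geometric mean over
    samples, using genes with positive counts in every sample). The upper
    and lower quartiles of M are trimmed; the surviving values are averaged
    with weights ``w_g = 1 / sqrt(1/x_gs + 1/ref_g)`` — the inverse of the
    delta-method SD of a log count under Poisson noise — giving
    ``log2 c_s``. The factors therefore satisfy, by construction, the
    defining identity that the trimmed weighted mean of ``M_g - log2 c_s``
    vanishes.

    Returns the size factors and the normalized log2 matrix
    ``log2(x_gs) - log2(c_s)``; zero counts get ``pseudocount`` before the
    log and are excluded from factor estimation.
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    all_pos = (X > 0).all(axis=1)
    if int(all_pos.sum()) < min_genes:
        raise NormalizationError(
            f"only {int(all_pos.sum())} genes positive in all samples (need {min_genes})"
        )
    sub = X[all_pos]
    ref = np.exp(np.log(sub).mean(axis=1))  # geometric mean over samples
    genes_used = counts.index[all_pos]

    log2c = np.empty(X.shape[1])
    detail: dict[str, pd.DataFrame] = {}
    for j, sample in enumerate(counts.columns):
        x = sub[:, j]
        M = np.log2(x / ref)
        w = 1.0 / np.sqrt(1.0 / x + 1.0 / ref)
        lo, hi = np.percentile(M, [25.0, 75.0])
        keep = (M >= lo) & (M <= hi)
        log2c[j] = float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        detail[str(sample)] = pd.DataFrame(
            {"M": M, "w": w, "trimmed": ~keep}, index=genes_used
        )

    factors = pd.Series(2.0**log2c, index=counts.columns, name="c")
    logx = np.log2(np.where(X > 0, X, pseudocount))
    norm = pd.DataFrame(
        logx - log2c[None, :], index=counts.index, columns=counts.columns
    )
    return SizeFactors(factors=factors, detail=detail, n_genes_used=len(genes_used)), norm


def replicate_concordance(
    lib1: np.ndarray, lib2: np.ndarray, coverage: float = 0.99
) -> float:
    """Fraction of genes consistent with pure Poisson noise between replicates.

    Conditional on the gene total ``n = x1 + x2``, ``x1`` under the Poisson
    null is Binomial(n, p) with ``p = N1/(N1+N2)`` set by the library
    totals. A gene is concordant iff x1 lies inside the central (equal-tail)
    ``coverage`` region of that binomial. Genes with ``n = 0`` are skipped.
    """
    x1 = np.asarray(lib1, dtype=float)
    x2 = np.asarray(lib2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("libraries must have equal length")
    n1, n2 = x1.sum(), x2.sum()
    if n1 + n2 <= 0:
        raise ValueError("both libraries are empty")
    n = x1 + x2
    mask = n > 0
    p = n1 / (n1 + n2)
    tail = (1.0 - coverage) / 2.0
    lo = stats.binom.ppf(tail, n[mask], p)
    hi = stats.binom.ppf(1.0 - tail, n[mask], p)
    ok = (x1[mask] >= lo) & (x1[mask] <= hi)
    return float(ok.mean())


# ---------------------------------------------------------------------------
# g-factor screen


def _target_bin(n: int, interval_h: float, target_period_h: float) -> int:
    duration = n * interval_h
    kf = duration / target_period_h
    k = int(round(kf))
    if abs(kf - k) > 1e-9 or k < 1 or k > n // 2:
        raise ValueError(
            f"period {target_period_h} h not on the natural FFT grid of a "
            f"{n}-point, {interval_h}-h series"
        )
    return k


def g_factor(
    series: np.ndarray,
    interval_h: float = 4.0,
    target_period_h: float = 24.0,
    include_harmonics: bool = False,
) -> float:
    """Rhythmicity score: 24-h power over total power, in [0, 1].

    The series is mean-centered, so the DC term never enters; powers are
    taken on the series' natural FFT grid (one-sided, up to Nyquist). With
    ``include_harmonics`` the numerator also sums the on-grid harmonics
    (2x, 3x, ... the 24-h frequency). A constant series scores 0.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short (need >= 4 points)")
    k = _target_bin(n, interval_h, target_period_h)
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        return 0.0
    power = np.abs(np.fft.rfft(xc)) ** 2
    total = float(power[1:].sum())
    num = float(power[k::k].sum()) if include_harmonics else float(power[k])
    return num / total


def g_factor_table(
    matrix: pd.DataFrame, interval_h: float = 4.0, target_period_h: float = 24.0
) -> GFactorTable:
    """Per-gene g-factors (fundamental and harmonics variant) for a matrix.

    Rows are genes, columns time-ordered samples (typically the normalized
    log2 matrix, replicates collapsed).
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    k = _target_bin(n, interval_h, target_period_h)
    Xc = X - X.mean(axis=1, keepdims=True)
    degenerate = np.isclose(np.abs(Xc).max(axis=1), 0.0)
    power = np.abs(np.fft.rfft(Xc, axis=1)) ** 2
    total = power[:, 1:].sum(axis=1)
    total = np.where(total > 0, total, 1.0)
    g = power[:, k] / total
    g_harm = power[:, k::k].sum(axis=1) / total
    g[degenerate] = 0.0
    g_harm[degenerate] = 0.0
    table = pd.DataFrame(
        {"g": g, "g_harmonic": g_harm, "degenerate": degenerate}, index=matrix.index
    )
    return GFactorTable(table=table, harmonics_included=True)


def select_dcgs(gtable: GFactorTable | pd.DataFrame, cutoff: float = 0.5) -> pd.Index:
    """Diel cycle genes: strictly ``g > cutoff`` on the fundamental score."""
    table = gtable.table if isinstance(gtable, GFactorTable) else gtable
    return table.index[table["g"] > cutoff]


# ---------------------------------------------------------------------------
# phase estimation and clustering


def estimate_peak_zt(
    profile: np.ndarray,
    interval_h: float = 4.0,
    start_zt: float = 1.0,
    target_period_h: float = 24.0,
) -> float:
    """Peak ZT from the phase of the 24-h DFT component.

    A pure cosine peaking at ZT p returns p exactly. Returns ``nan`` when
    the 24-h component is degenerate (zero power).
    """
    x = np.asarray(profile, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("profile too short")
    k = _target_bin(n, interval_h, target_period_h)
    xc = x - x.mean()
    coef = np.fft.rfft(xc)[k]
    if abs(coef) <= 1e-12 * max(1.0, float(np.abs(xc).max())) * n:
        return float("nan")
    theta = math.atan2(coef.imag, coef.real)
    return (start_zt - target_period_h * theta / (2.0 * math.pi)) % target_period_h


def _circular_mean_zt(zts: np.ndarray) -> float:
    ang = 2.0 * np.pi * np.asarray(zts, float) / 24.0
    m = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (24.0 * m / (2.0 * np.pi)) % 24.0


def kmeans_phase_clusters(
    profiles: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    restarts: int = 50,
    interval_h: float = 4.0,
    start_zt: float = 1.0,
) -> ClusterResult:
    """Cluster z-scored DCG profiles into K phase groups.

    Each gene's profile is z-scored (so only temporal shape matters), then
    Euclidean K-means is run with ``restarts`` seeded initializations,
    keeping the lowest within-cluster sum of squares. Clusters are
    relabeled 1..K by ascending circular-mean peak ZT of their members so
    labels follow the diel cycle.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = sd[:, 0] <= 0
    sd[flat] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw_labels = km.fit_predict(Z)

    peaks = np.array(
        [estimate_peak_zt(row, interval_h=interval_h, start_zt=start_zt) for row in X]
    )
    order_keys = []
    for c in range(k):
        member_peaks = peaks[(raw_labels == c) & ~np.isnan(peaks)]
        key = _circular_mean_zt(member_peaks) if member_peaks.size else float("inf")
        order_keys.append(key)
    order = np.argsort(order_keys, kind="stable")
    relabel = {int(old): i + 1 for i, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw_labels])

    assignment = pd.Series(labels, index=profiles.index, name="cluster")
    cluster_profiles = pd.DataFrame(
        {c: X[labels == c].mean(axis=0) if (labels == c).any() else np.full(X.shape[1], np.nan)
         for c in range(1, k + 1)},
        index=profiles.columns,
    ).T
    cluster_peak = pd.Series(
        {
            c: (
                _circular_mean_zt(peaks[(labels == c) & ~np.isnan(peaks)])
                if ((labels == c) & ~np.isnan(peaks)).any()
                else float("nan")
            )
            for c in range(1, k + 1)
        },
        name="peak_zt",
    )
    empty = [c for c in range(1, k + 1) if not (labels == c).any()]
    return ClusterResult(
        assignment=assignment,
        k=k,
        seed=seed,
        restarts=restarts,
        cluster_profiles=cluster_profiles,
        cluster_peak_zt=cluster_peak,
        empty=empty,
    )


# ---------------------------------------------------------------------------
# sample-label helpers

_LABEL_RE = re.compile(r"^ZT(?P<zt>\d+(?:\.\d+)?)_day(?P<day>\d+)(?:_rep(?P<rep>\d+))?$")


def parse_sample_label(label: str) -> tuple[float, int]:
    """Parse ``ZT<h>_day<d>[_rep<r>]`` into (zt, day)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse sample label {label!r} (expect ZT<h>_day<d>)")
    return float(m.group("zt")), int(m.group("day"))


def sample_zt_hours(columns: list[str]) -> np.ndarray:
    """Cumulative ZT hours (day 1 ZT1 -> 1, day 2 ZT1 -> 25) per column."""
    out = []
    for c in columns:
        zt, day = parse_sample_label(str(c))
        out.append(zt + 24.0 * (day - 1))
    return np.asarray(out)


def collapse_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns (same ZT and day) after normalization.

    Columns whose labels differ only in a ``_rep<r>`` suffix are averaged
    and the suffix dropped; column order follows time.
    """
    base = {}
    for c in matrix.columns:
        zt, day = parse_sample_label(str(c))
        zt_str = f"{zt:g}"
        base.setdefault((day, zt, f"ZT{zt_str}_day{day}"), []).append(c)
    keys = sorted(base)
    data = {name: matrix[cols].mean(axis=1) for (_, _, name), cols in base.items()}
    ordered = [name for (_, _, name) in keys]
    return pd.DataFrame(data)[ordered]
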