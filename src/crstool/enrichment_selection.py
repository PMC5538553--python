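"""Stratified interval-enrichment Z-test, conserved-site Fisher test and the
purifying-selection ratio rule."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from crstool.io_formats import GenomeWindows, Interval, IntervalSet, merge_intervals

MIN_FEATURE_COVERAGE = 1000  # bases a feature must cover within a bin


@dataclass
class EnrichmentResult:
    """One bin's overlap test: q of n midpoints hit features of background
    probability p; z = (q - np) / sqrt(np(1-p)), one-sided upper tail."""

    q: int
    n: int
    p: float
    z: float
    pvalue: float
    fe: float
    bin: str = ""
    qvalue: float = float("nan")


@dataclass
class SelectionRatios:
    d_crs: float
    d_ar: float
    d_inter: float
    r1: float
    r2: float
    purifying: bool


def overlap_count(crs: IntervalSet, features: IntervalSet) -> int:
    """Number of CRS intervals whose midpoint falls inside any feature
    (half-open containment, strand ignored)."""
    merged = merge_intervals(features)
    by_chrom: dict[str, list[Interval]] = {}
    for rec in merged:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    q = 0
    for rec in crs:
        mid = rec.midpoint
        for f in by_chrom.get(rec.chrom, ()):
            if f.start <= mid < f.end:
                q += 1
                break
    return q


def enrichment_ztest(q: int, n: int, p: float, coverage: int | None = None) -> tuple[float, float]:
    """Normal approximation to the binomial: z = (q-np)/sqrt(np(1-p)),
    one-sided upper-tail p-value. Refuses bins whose feature coverage is
    below 1 kb (returns (nan, nan))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("background probability must lie strictly in (0,1)")
    if coverage is not None and coverage < MIN_FEATURE_COVERAGE:
        warnings.warn(f"feature coverage {coverage} < {MIN_FEATURE_COVERAGE} bases; test not calculated")
        return float("nan"), float("nan")
    z = (q - n * p) / np.sqrt(n * p * (1.0 - p))
    return float(z), float(stats.norm.sf(z))


def fold_enrichment(q: int, n: int, p: float) -> float:
    if p <= 0:
        raise ValueError("background probability must be positive")
    return q / (n * p)


def bh_correct(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (NaN entries passed through)."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0,1]")
    q = np.full_like(p, np.nan)
    idx = np.flatnonzero(finite)
    m = len(idx)
    if m:
        order = idx[np.argsort(p[idx])]
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q[order] = np.minimum(ranked, 1.0)
    return q.tolist()


def _bin_label(lo: float, hi: float) -> str:
    return f"[{lo:g},{hi:g})"


def stratified_enrichment(
    crs: IntervalSet,
    features: IntervalSet,
    windows: GenomeWindows,
    gc_bins: Sequence[float],
    si_bins: Sequence[float],
) -> list[EnrichmentResult]:
    """Enrichment per (GC, SI) bin of the genome windows.

    Each CRS is assigned to the bin of the window containing its midpoint;
    per-bin background p is the fraction of the bin's window bases covered by
    (merged) features; q-values are BH-corrected across the bin grid."""
    gc_edges = np.asarray(gc_bins, float)
    si_edges = np.asarray(si_bins, float)
    merged = merge_intervals(features)
    feat_by_chrom: dict[str, list[Interval]] = {}
    for rec in merged:
        feat_by_chrom.setdefault(rec.chrom, []).append(rec)

    def covered_bases(win: Interval) -> int:
        tot = 0
        for f in feat_by_chrom.get(win.chrom, ()):
            tot += max(0, min(win.end, f.end) - max(win.start, f.start))
        return tot

    def bin_of(gc: float, si: float) -> tuple[int, int]:
        g = min(max(int(np.searchsorted(gc_edges, gc, side="right")) - 1, 0), len(gc_edges) - 2)
        s = min(max(int(np.searchsorted(si_edges, si, side="right")) - 1, 0), len(si_edges) - 2)
        return g, s

    win_bins = [bin_of(g, s) for g, s in zip(windows.gc, windows.si)]
    bin_cov: dict[tuple[int, int], int] = {}
    bin_size: dict[tuple[int, int], int] = {}
    for rec, b in zip(windows.intervals, win_bins):
        bin_cov[b] = bin_cov.get(b, 0) + covered_bases(rec)
        bin_size[b] = bin_size.get(b, 0) + len(rec)

    # locate each CRS midpoint's window -> bin
    win_by_chrom: dict[str, list[tuple[Interval, tuple[int, int]]]] = {}
    for rec, b in zip(windows.intervals, win_bins):
        win_by_chrom.setdefault(rec.chrom, []).append((rec, b))
    bin_q: dict[tuple[int, int], int] = {}
    bin_n: dict[tuple[int, int], int] = {}
    for rec in crs:
        mid = rec.midpoint
        for win, b in win_by_chrom.get(rec.chrom, ()):
            if win.start <= mid < win.end:
                bin_n[b] = bin_n.get(b, 0) + 1
                hit = any(
                    f.start <= mid < f.end for f in feat_by_chrom.get(rec.chrom, ())
                )
                if hit:
                    bin_q[b] = bin_q.get(b, 0) + 1
                break

    results: list[EnrichmentResult] = []
    for b in sorted(bin_n):
        n = bin_n[b]
        size = bin_size.get(b, 0)
        cov = bin_cov.get(b, 0)
        if size == 0 or cov == 0 or cov == size:
            continue  # empty or degenerate bin: background p not in (0,1)
        p = cov / size
        q = bin_q.get(b, 0)
        z, pv = enrichment_ztest(q, n, p, coverage=cov)
        g, s = b
        label = f"gc={_bin_label(gc_edges[g], gc_edges[g + 1])},si={_bin_label(si_edges[s], si_edges[s + 1])}"
        results.append(
            EnrichmentResult(q=q, n=n, p=p, z=z, pvalue=pv, fe=fold_enrichment(q, n, p), bin=label)
        )
    qvals = bh_correct([r.pvalue for r in results])
    for r, qv in zip(results, qvals):
        r.qvalue = qv
    return results


def conserved_site_fet(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the 2x2 table
    [[a, b], [c, d]]; odds ratio ad/bc (inf when bc == 0)."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def selection_ratio(d_crs: float, d_ar: float, d_inter: float, cutoff: float = 0.95) -> SelectionRatios:
    """Purifying selection iff d_crs/d_ar < cutoff and d_crs/d_inter < cutoff."""
    if d_ar <= 0 or d_inter <= 0:
        raise ValueError("reference distances must be positive")
    if d_crs < 0:
        raise ValueError("distances must be non-negative")
    r1 = d_crs / d_ar
    r2 = d_crs / d_inter
    return SelectionRatios(
        d_crs=d_crs,
        d_ar=d_ar,
        d_inter=d_inter,
        r1=r1,
        r2=r2,
        purifying=bool(r1 < cutoff and r2 < cutoff),
    )
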