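"""Expression calls, RLE normalization, CaptureSeq read islands, exosome
stability, and structure-probing pairing calls.

Empirical p-values use add-one smoothing so p is never 0. Probing calls
follow the fixed rule lfc = log2(denatured'+5) - log2(native'+5) > 1 on
depth-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from crstool.io_formats import Interval, IntervalSet

PROBING_PSEUDOCOUNT = 5.0
PROBING_CUTOFF = 1.0
EXPRESSION_P = 0.01
ISLAND_P = 0.1
STABLE_MAX = 0.25
UNSTABLE_MIN = 0.75


def empirical_pvalue(observed: float, background: Sequence[float]) -> float:
    """p = (1 + #{background >= observed}) / (1 + |background|)."""
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background distribution")
    return float((1 + np.sum(bg >= observed)) / (1 + bg.size))


@dataclass
class CountMatrix:
    """Feature x sample counts with RLE size factors and CPM/RLE values."""

    counts: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    size_factors: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(self.counts.shape[0])]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(self.counts.shape[1])]


def cpm_rle_normalize(m: CountMatrix) -> CountMatrix:
    """Median-of-ratios (RLE) size factors, then counts-per-million on
    effective library sizes (library size x size factor)."""
    counts = np.asarray(m.counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("RLE normalization needs >= 2 samples")
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError("no feature has positive counts in every sample")
    ref = np.exp(np.mean(np.log(counts[allpos]), axis=1))  # geometric means
    ratios = counts[allpos] / ref[:, None]
    size_factors = np.median(ratios, axis=0)
    libsize = counts.sum(axis=0)
    normalized = counts / (libsize * size_factors)[None, :] * 1e6
    return CountMatrix(
        counts=m.counts,
        feature_ids=m.feature_ids,
        sample_ids=m.sample_ids,
        size_factors=size_factors,
        normalized=normalized,
    )


@dataclass
class ExpressionCall:
    feature_id: str
    count: float
    empirical_p: float
    expressed: bool


def expression_calls(
    counts: Sequence[float],
    background: Sequence[float],
    feature_ids: Sequence[str] | None = None,
    alpha: float = EXPRESSION_P,
) -> list[ExpressionCall]:
    """Expressed iff the empirical p-value against random-locus background
    counts is below alpha (default 0.01)."""
    ids = list(feature_ids) if feature_ids else [f"f{i}" for i in range(len(counts))]
    out = []
    for fid, c in zip(ids, counts):
        p = empirical_pvalue(c, background)
        out.append(ExpressionCall(feature_id=fid, count=c, empirical_p=p, expressed=p < alpha))
    return out


def coexpression(profile_a: Sequence[float], profile_b: Sequence[float], strong_at: float = 0.8) -> tuple[float, bool]:
    """Pearson correlation of two expression profiles and the strong-coexpression flag."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        return float("nan"), False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r >= strong_at


# ---------------------------------------------------------------------------
# CaptureSeq read islands


@dataclass
class ReadIsland:
    interval: Interval
    strand: str
    read_count: int
    on_target: bool = False
    empirical_p: float = float("nan")
    expressed: bool = False


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def call_islands(
    reads: IntervalSet,
    repeats: IntervalSet | None = None,
    probes: IntervalSet | None = None,
    extension: int = 150,
    alpha: float = ISLAND_P,
) -> list[ReadIsland]:
    """CaptureSeq island calling.

    Reads overlapping a repeat by >= 50% of their length are dropped; the
    rest are replaced by ``extension``-nt intervals anchored at their 5' end
    in reading direction; overlapping unified reads on one strand merge into
    islands carrying their read counts. Islands are on-target when they
    overlap a probe by >= 1 bp; empirical p-values come from the off-target
    island count distribution (expressed at p < 0.1).
    """
    rep_by_chrom: dict[str, list[Interval]] = {}
    if repeats:
        for r in repeats:
            rep_by_chrom.setdefault(r.chrom, []).append(r)

    unified: list[Interval] = []
    for rec in reads:
        if rec.strand not in "+-":
            raise ValueError(f"read {rec} has no strand")
        rlen = len(rec)
        if any(
            _overlap(rec.start, rec.end, rp.start, rp.end) * 2 >= rlen
            for rp in rep_by_chrom.get(rec.chrom, ())
        ):
            continue
        if rec.strand == "+":
            iv = Interval(rec.chrom, rec.start, rec.start + extension, rec.name, 0, "+")
        else:
            iv = Interval(rec.chrom, max(0, rec.end - extension), rec.end, rec.name, 0, "-")
        unified.append(iv)

    islands: list[ReadIsland] = []
    for strand in "+-":
        group = sorted(
            (iv for iv in unified if iv.strand == strand),
            key=lambda r: (r.chrom, r.start, r.end),
        )
        cur: list[Interval] = []
        for iv in group:
            if cur and cur[-1].chrom == iv.chrom and iv.start < max(c.end for c in cur):
                cur.append(iv)
            else:
                if cur:
                    islands.append(_make_island(cur, strand))
                cur = [iv]
        if cur:
            islands.append(_make_island(cur, strand))

    if probes:
        probe_by_chrom: dict[str, list[Interval]] = {}
        for pr in probes:
            probe_by_chrom.setdefault(pr.chrom, []).append(pr)
        for isl in islands:
            isl.on_target = any(
                _overlap(isl.interval.start, isl.interval.end, pr.start, pr.end) >= 1
                for pr in probe_by_chrom.get(isl.interval.chrom, ())
            )
        off_counts = [isl.read_count for isl in islands if not isl.on_target]
        if off_counts:
            for isl in islands:
                isl.empirical_p = empirical_pvalue(isl.read_count, off_counts)
                isl.expressed = isl.on_target and isl.empirical_p < alpha
    return islands


def _make_island(unified: list[Interval], strand: str) -> ReadIsland:
    start = min(iv.start for iv in unified)
    end = max(iv.end for iv in unified)
    return ReadIsland(
        interval=Interval(unified[0].chrom, start, end, ".", 0, strand),
        strand=strand,
        read_count=len(unified),
    )


# ---------------------------------------------------------------------------
# Transcript stability


@dataclass
class StabilityCall:
    e_exo: float
    e_ctr: float
    s: float
    klass: str


def exosome_sensitivity(e_exo: float, e_ctr: float) -> StabilityCall:
    """s = max((E_exo - E_ctr)/E_exo, 0); stable at s <= 0.25, unstable at
    s >= 0.75, intermediate otherwise."""
    if e_exo <= 0:
        raise ValueError("E_exo must be positive")
    s = max((e_exo - e_ctr) / e_exo, 0.0)
    if s <= STABLE_MAX:
        klass = "stable"
    elif s >= UNSTABLE_MIN:
        klass = "unstable"
    else:
        klass = "intermediate"
    return StabilityCall(e_exo=e_exo, e_ctr=e_ctr, s=s, klass=klass)


# ---------------------------------------------------------------------------
# Structure probing


@dataclass
class ProbingProfile:
    lfc: np.ndarray
    paired_call: np.ndarray
    native: np.ndarray
    denatured: np.ndarray

    def __len__(self) -> int:
        return self.lfc.size


def probing_lfc(
    native: Sequence[float],
    denatured: Sequence[float],
    depth_native: float = 1.0,
    depth_denatured: float = 1.0,
    pseudocount: float = PROBING_PSEUDOCOUNT,
    cutoff: float = PROBING_CUTOFF,
) -> ProbingProfile:
    """Per-position lfc = log2(denatured' + k) - log2(native' + k) on
    depth-normalized counts (k = 5); paired iff lfc > 1 (strict)."""
    nat = np.asarray(native, dtype=float)
    den = np.asarray(denatured, dtype=float)
    if nat.shape != den.shape:
        raise ValueError("native and denatured count vectors differ in length")
    if depth_native <= 0 or depth_denatured <= 0:
        raise ValueError("depths must be positive")
    nat_n = nat / depth_native
    den_n = den / depth_denatured
    lfc = np.log2(den_n + pseudocount) - np.log2(nat_n + pseudocount)
    return ProbingProfile(lfc=lfc, paired_call=lfc > cutoff, native=nat, denatured=den)


def probing_concordance(structure, profile: ProbingProfile) -> float:
    """Fraction of structure-paired positions (1-based) called paired by the
    probing profile."""
    positions = sorted({c for ij in structure.pairs for c in ij})
    if not positions:
        raise ValueError("structure has no paired positions")
    if positions[-1] > len(profile):
        raise ValueError("structure positions exceed profile length")
    calls = profile.paired_call[[p - 1 for p in positions]]
    return float(np.mean(calls))
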