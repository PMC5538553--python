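"""Dinucleotide-controlled null alignments and GC-binned FDR estimation.

Two transparent null modes bracket a full simultaneous-fit simulator: a joint
column shuffle (conserves every column, destroys pairing geometry) and a
GC-matched phylogenetic re-simulation reusing the source gap mask. FDR for a
score threshold within a GC bin is the ratio of null to real calls, clipped
to [0,1], averaged over replicate null ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from crstool.io_formats import AnnotatedAlignment, alignment_stats
from crstool.phylo_models import NUC, PhyloTree, build_gtr, evolve_states


# ---------------------------------------------------------------------------
# Dinucleotide shuffle (Altschul–Erickson Eulerian walk)


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Shuffle preserving exact mono- and dinucleotide counts.

    Classic Eulerian-walk construction: the sequence is a walk on the
    dinucleotide multigraph; a random last-edge arborescence into the final
    vertex is drawn (rejection sampling), remaining out-edges are permuted,
    and the walk is replayed.
    """
    if len(seq) < 2:
        return seq
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    letters = sorted(set(seq))
    if len(letters) == 1:
        return seq
    edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]

    non_terminal = [c for c in letters if c != last and edges[c]]
    for _ in range(10000):
        last_edge = {c: edges[c][rng.integers(len(edges[c]))] for c in non_terminal}
        # the chosen last edges must form a tree rooted at `last`
        ok = True
        for c in non_terminal:
            seen = {c}
            cur = c
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    # reached a vertex with no out-edges (== last only) or a cycle
                    ok = cur == last
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop essentially always terminates
        raise RuntimeError("could not sample a valid shuffle")

    out_lists: dict[str, list[str]] = {}
    for c in letters:
        rest = list(edges[c])
        tail = []
        if c in last_edge:
            rest.remove(last_edge[c])
            tail = [last_edge[c]]
        rng.shuffle(rest)
        out_lists[c] = rest + tail

    walk = [first]
    ptr = {c: 0 for c in letters}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def dinucleotide_shuffle_alignment(aln: AnnotatedAlignment, seed: int) -> AnnotatedAlignment:
    """Per-row dinucleotide shuffle of the ungapped sequence, re-inserted into
    the row's original gap mask; the structure annotation is kept only as a
    set of column positions to score."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, seq in aln.rows:
        ungapped = seq.replace("-", "")
        shuffled = dinucleotide_shuffle(ungapped, rng)
        it = iter(shuffled)
        rows.append((name, "".join(next(it) if c != "-" else "-" for c in seq)))
    return AnnotatedAlignment(rows=rows, structure=aln.structure, id=f"{aln.id}|dishuffle")


# ---------------------------------------------------------------------------
# Null alignments


@dataclass
class NullEnsemble:
    alignments: list[AnnotatedAlignment]
    mode: str
    seed: int
    source_id: str


def simulate_null_alignment(
    aln: AnnotatedAlignment,
    tree: PhyloTree | None,
    mode: str,
    seed: int,
) -> AnnotatedAlignment:
    """One null alignment with the source's dimensions.

    mode='shuffle': permute alignment columns jointly (column multiset and
    per-row gap counts preserved exactly). mode='evolve': re-simulate leaf
    sequences down the tree under a GTR whose stationary GC matches the
    source alignment, reusing the source gap mask. The structure line is
    carried over as scoring positions only (same column geometry).
    """
    rng = np.random.default_rng(seed)
    if mode == "shuffle":
        L = aln.length
        perm = rng.permutation(L)
        rows = [(name, "".join(seq[k] for k in perm)) for name, seq in aln.rows]
        return AnnotatedAlignment(rows=rows, structure=aln.structure, id=f"{aln.id}|null-shuffle")
    if mode == "evolve":
        if tree is None:
            raise ValueError("evolve mode requires a tree")
        gc, _, L, _ = alignment_stats(aln)
        gc = min(max(gc, 0.02), 0.98)
        pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        model = build_gtr(pi, np.ones(6))
        states = evolve_states(tree, model, L, rng)
        leaf_order = {name: r for r, name in enumerate(tree.leaves)}
        rows = []
        for name, seq in aln.rows:
            sim = states[leaf_order[name]]
            rows.append(
                (name, "".join("-" if c == "-" else NUC[sim[k]] for k, c in enumerate(seq)))
            )
        return AnnotatedAlignment(rows=rows, structure=aln.structure, id=f"{aln.id}|null-evolve")
    raise ValueError(f"unknown null mode {mode!r}")


def null_ensemble(
    aln: AnnotatedAlignment,
    tree: PhyloTree | None,
    mode: str,
    n_replicates: int,
    seed: int,
) -> NullEnsemble:
    """Deterministic ensemble: replicate r uses seed derived from (seed, r)."""
    alns = [
        simulate_null_alignment(aln, tree, mode, seed=_derive_seed(seed, r))
        for r in range(n_replicates)
    ]
    return NullEnsemble(alignments=alns, mode=mode, seed=seed, source_id=aln.id)


def _derive_seed(seed: int, replicate: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)).generate_state(1)[0])


# ---------------------------------------------------------------------------
# FDR


DEFAULT_GC_BINS = (0.0, 0.2, 0.4, 0.65, 0.8, 1.0)


@dataclass
class FDRTable:
    """GC-bin x threshold grid of estimated FDRs (NaN where undefined)."""

    gc_bins: tuple[float, ...]
    thresholds: tuple[float, ...]
    fdr_mean: np.ndarray  # (n_bins, n_thresholds)
    fdr_sd: np.ndarray
    n_real: np.ndarray
    n_null: np.ndarray

    @property
    def bin_labels(self) -> list[str]:
        lo, hi = self.gc_bins[:-1], self.gc_bins[1:]
        return [f"[{a:g},{b:g})" for a, b in zip(lo, hi)]

    def threshold_at_fdr(self, target_fdr: float, gc: float | None = None) -> float | None:
        """Smallest threshold whose estimated mean FDR is <= target.

        With ``gc`` given, uses that GC bin; otherwise pools bins by summing
        counts. Returns None if no threshold qualifies."""
        if gc is not None:
            b = assign_bin(gc, self.gc_bins)
            means = self.fdr_mean[b]
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.clip(
                    self.n_null.sum(axis=0) / np.maximum(self.n_real.sum(axis=0), 1e-300), 0, 1
                )
                means[self.n_real.sum(axis=0) == 0] = np.nan
        for t, m in zip(self.thresholds, means):
            if np.isfinite(m) and m <= target_fdr:
                return float(t)
        return None

    def to_frame(self):
        import pandas as pd

        rows = []
        for b, label in enumerate(self.bin_labels):
            for k, t in enumerate(self.thresholds):
                rows.append(
                    {
                        "gc_bin": label,
                        "threshold": t,
                        "fdr_mean": self.fdr_mean[b, k],
                        "fdr_sd": self.fdr_sd[b, k],
                        "n_real": int(self.n_real[b, k]),
                        "n_null": int(self.n_null[b, k]),
                    }
                )
        return pd.DataFrame(rows)


def assign_bin(gc: float, gc_bins) -> int:
    edges = np.asarray(gc_bins)
    b = int(np.searchsorted(edges, gc, side="right") - 1)
    return min(max(b, 0), len(edges) - 2)


def estimate_fdr(
    real,
    null,
    thresholds,
    gc_bins=DEFAULT_GC_BINS,
    n_replicates: int = 1,
) -> FDRTable:
    """Per (GC bin, threshold): FDR = min(1, N_null>=t / N_real>=t).

    ``real`` and ``null`` are sequences of (pscore, gc); ``null`` holds
    ``n_replicates`` ensembles of the same size as ``real`` concatenated (or
    a list of per-replicate lists). Mean and SD are taken over replicates;
    cells with no real calls are NaN.
    """
    real = list(real)
    if null and isinstance(null[0], (list, tuple)) and null[0] and isinstance(null[0][0], (list, tuple)):
        reps = [list(r) for r in null]
        n_replicates = len(reps)
    else:
        null = list(null)
        if n_replicates < 1 or len(null) % n_replicates:
            raise ValueError("null list does not divide into n_replicates equal groups")
        step = len(null) // n_replicates
        reps = [null[r * step : (r + 1) * step] for r in range(n_replicates)]

    thresholds = tuple(float(t) for t in thresholds)
    gc_bins = tuple(float(b) for b in gc_bins)
    nb, nt = len(gc_bins) - 1, len(thresholds)

    def counts(scores) -> np.ndarray:
        m = np.zeros((nb, nt))
        for s, gc in scores:
            b = assign_bin(gc, gc_bins)
            for k, t in enumerate(thresholds):
                if s >= t:
                    m[b, k] += 1
        return m

    n_real = counts(real)
    per_rep = np.stack([counts(rep) for rep in reps])  # (R, nb, nt)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.clip(per_rep / n_real[None, :, :], 0.0, 1.0)
    fdr[np.broadcast_to(n_real == 0, fdr.shape)] = np.nan
    if np.any(n_real == 0):
        warnings.warn("some (GC bin, threshold) cells have no real calls; reported as NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(fdr, axis=0) if len(reps) else np.full((nb, nt), np.nan)
        sd = np.nanstd(fdr, axis=0, ddof=1) if len(reps) > 1 else np.zeros((nb, nt))
    mean = np.where(n_real == 0, np.nan, mean)
    return FDRTable(
        gc_bins=gc_bins,
        thresholds=thresholds,
        fdr_mean=mean,
        fdr_sd=sd,
        n_real=n_real,
        n_null=per_rep.sum(axis=0),
    )
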