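"""Equilibrium base-pair probabilities from a minimal pair-energy model.

The model assigns one energy per canonical pair type (no stacking, dangles or
lonely-pair terms), so the partition function runs over all pseudoknot-free
structures with Boltzmann weight exp(-beta * sum of pair energies). This keeps
every probability checkable against exhaustive structure enumeration while the
provider interface lets a full nearest-neighbour engine be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

CANONICAL = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair-type energies (GC strongest), minimum hairpin size h, and
    inverse-temperature scale beta."""

    e_gc: float = -3.0
    e_au: float = -2.0
    e_gu: float = -1.0
    h: int = 3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.e_gc <= self.e_au <= self.e_gu < 0):
            raise ValueError("expect e_gc <= e_au <= e_gu < 0")
        if self.h < 1:
            raise ValueError("minimum hairpin size must be >= 1")

    def pair_weight(self, a: str, b: str) -> float:
        """Boltzmann factor of pairing bases a and b; 0 if non-canonical."""
        kind = CANONICAL.get((a, b))
        if kind is None:
            return 0.0
        e = {"GC": self.e_gc, "AU": self.e_au, "GU": self.e_gu}[kind]
        return float(np.exp(-self.beta * e))


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass
class PairProbMatrix:
    """Upper-triangular matrix of pairing probabilities for one sequence.

    ``p[i-1, j-1]`` is the probability that positions i<j (1-based) pair."""

    p: np.ndarray

    def __post_init__(self) -> None:
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise ValueError("probability matrix must be square")

    @property
    def n(self) -> int:
        return self.p.shape[0]

    def prob(self, i: int, j: int) -> float:
        """Pairing probability of 1-based positions i < j."""
        if not 1 <= i < j <= self.n:
            raise IndexError(f"positions ({i},{j}) out of range 1..{self.n}")
        return float(self.p[i - 1, j - 1])

    def unpaired(self) -> np.ndarray:
        """Per-position probability of being unpaired."""
        return 1.0 - self.p.sum(axis=1) - self.p.sum(axis=0)


def _pair_weights(seq: str, em: EnergyModel) -> np.ndarray:
    n = len(seq)
    q = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i + em.h + 1, n + 1):
            q[i, j] = em.pair_weight(seq[i - 1], seq[j - 1])
    return q


def basepair_probabilities(seq: str, em: EnergyModel = DEFAULT_ENERGY_MODEL) -> PairProbMatrix:
    """McCaskill-style inside/outside recursion for the pair-energy model.

    Returns the matrix of Boltzmann-averaged pair indicators over all
    pseudoknot-free structures of ``seq`` (positions 1-based in reports)."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    q = _pair_weights(seq, em)

    # inside: Z[i, j] = partition function of subsequence [i..j]; empty = 1.
    # Conditioning on the pairing partner of j gives, for fixed j,
    #   Z[i, j] = Z[i, j-1] + sum_{k >= i} c_k * Z[i, k-1],
    # with c_k = q[k, j] * Z[k+1, j-1]; vectorized over i as a masked matvec.
    Z = np.ones((n + 2, n + 2))
    for j in range(1, n + 1):
        Z[1 : j + 1, j] = Z[1 : j + 1, j - 1]
        ks = np.arange(1, j + 1)
        c = q[ks, j] * Z[ks + 1, j - 1]
        if np.any(c):
            A = Z[1 : j + 1, 0:j].copy()  # A[i-1, k-1] = Z[i, k-1]
            ii = np.arange(1, j + 1)
            A[ii[:, None] > ks[None, :]] = 0.0  # pair start k must be >= i
            Z[1 : j + 1, j] += A @ c
    Ztot = Z[1, n]

    # outside: Zhat[(i,j)] sums structures outside [i..j] given (i,j) paired;
    # the enclosing pair in the recursion is the innermost one.
    valid = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1) if q[i, j] > 0]
    p = np.zeros((n, n))
    if valid:
        valid.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
        vi = np.array([ij[0] for ij in valid])
        vj = np.array([ij[1] for ij in valid])
        vq = q[vi, vj]
        zhat = np.zeros(len(valid))
        for idx, (i, j) in enumerate(valid):
            out = Z[1, i - 1] * Z[j + 1, n]
            if idx > 0:
                enclosing = (vi[:idx] < i) & (vj[:idx] > j)
                if np.any(enclosing):
                    sel = np.flatnonzero(enclosing)
                    out += float(
                        np.sum(
                            vq[sel]
                            * zhat[sel]
                            * Z[vi[sel] + 1, i - 1]
                            * Z[j + 1, vj[sel] - 1]
                        )
                    )
            zhat[idx] = out
            zb = vq[idx] * Z[i + 1, j - 1]
            p[i - 1, j - 1] = zb * out / Ztot
    return PairProbMatrix(p=np.clip(p, 0.0, 1.0))


@lru_cache(maxsize=4096)
def _cached_bpp(seq: str, em: EnergyModel) -> PairProbMatrix:
    return basepair_probabilities(seq, em)


def alignment_pair_weight(aln, i: int, j: int, em: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Mean, over alignment rows, of each row's pairing probability at the
    sequence positions underlying columns i < j; a row gapped at either
    column contributes 0."""
    return alignment_pair_weights(aln, [(i, j)], em)[0]


def alignment_pair_weights(aln, pairs, em: EnergyModel = DEFAULT_ENERGY_MODEL) -> np.ndarray:
    """Thermodynamic weights for many column pairs at once (one partition
    function per row, cached by sequence)."""
    L = aln.length
    for i, j in pairs:
        if not 1 <= i < j <= L:
            raise IndexError(f"column pair ({i},{j}) outside 1..{L}")
    weights = np.zeros(len(pairs))
    n_rows = len(aln.rows)
    for name, seq in aln.rows:
        ungapped = seq.replace("-", "")
        if not ungapped:
            continue
        colpos = aln.column_to_position(name)
        bpp = _cached_bpp(ungapped, em)
        for k, (i, j) in enumerate(pairs):
            pi_, pj_ = colpos.get(i), colpos.get(j)
            if pi_ is None or pj_ is None:
                continue
            weights[k] += bpp.prob(pi_, pj_)
    return weights / n_rows
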