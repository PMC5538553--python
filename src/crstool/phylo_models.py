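"""Reversible substitution models and column likelihoods on a tree.

Two alphabets are supported: the four RNA bases and the sixteen ordered
dinucleotide (base-pair) states. Column likelihoods are computed by
Felsenstein pruning, vectorized over alignment columns; transition matrices
come from the eigendecomposition of the symmetrized reversible rate matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

NUC = "ACGU"
NUC_INDEX = {c: i for i, c in enumerate(NUC)}
PAIR16 = [a + b for a in NUC for b in NUC]
PAIR16_INDEX = {p: i for i, p in enumerate(PAIR16)}
CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
WATSON_CRICK = ("AU", "UA", "GC", "CG")
# order of the 6 GTR exchangeabilities
EXCH_ORDER = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

MISSING = -1


def _exch_matrix(exch, n: int, allow_zero: bool = False) -> np.ndarray:
    """Accept a flat upper-triangle vector or a full symmetric matrix."""
    exch = np.asarray(exch, dtype=float)
    if exch.ndim == 1:
        iu = np.triu_indices(n, k=1)
        if exch.shape[0] != len(iu[0]):
            raise ValueError(f"expected {len(iu[0])} exchangeabilities, got {exch.shape[0]}")
        m = np.zeros((n, n))
        m[iu] = exch
        m += m.T
    else:
        if exch.shape != (n, n):
            raise ValueError("exchangeability matrix has wrong shape")
        if not np.allclose(exch, exch.T):
            raise ValueError("exchangeability matrix must be symmetric")
        m = exch.copy()
        np.fill_diagonal(m, 0.0)
    off = m[~np.eye(n, dtype=bool)]
    if np.any(off < 0) or (not allow_zero and np.any(off == 0)):
        raise ValueError("exchangeabilities must be strictly positive")
    return m


class _ReversibleModel:
    """Shared machinery: Q from (pi, exch), eigendecomposition, P(t)."""

    pi: np.ndarray
    Q: np.ndarray

    def _build(self, pi, exch_m, target_rate: float = 1.0) -> None:
        pi = np.asarray(pi, dtype=float)
        n = pi.shape[0]
        if np.any(pi <= 0):
            raise ValueError("stationary frequencies must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"stationary frequencies sum to {pi.sum():.12f}, not 1")
        Q = exch_m * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.sum(pi * np.diag(Q)))
        if rate <= 0:
            raise ValueError("degenerate rate matrix")
        Q *= target_rate / rate
        self.pi = pi
        self.exch = exch_m * (target_rate / rate)
        self.Q = Q
        self.scale = 1.0
        self._decompose()

    def _decompose(self) -> None:
        sq = np.sqrt(self.pi)
        S = (self.Q * sq[None, :]) / sq[:, None]
        S = 0.5 * (S + S.T)  # kill rounding asymmetry
        w, U = np.linalg.eigh(S)
        self._eigval = w
        self._left = U.T * sq[None, :]       # U^T D
        self._right = U / sq[:, None]        # D^-1 U
        self._pcache: dict[float, np.ndarray] = {}

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = self._pcache.get(t)
        if P is None:
            P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            self._pcache[t] = P
        return P


def transition_matrix(model: "_ReversibleModel", t: float) -> np.ndarray:
    return model.transition_matrix(t)


@dataclass(init=False)
class RateModel(_ReversibleModel):
    """4-state general time-reversible model, normalized to rate 1."""

    pi: np.ndarray
    exch: np.ndarray
    Q: np.ndarray
    scale: float = 1.0

    alphabet = NUC
    state_index = NUC_INDEX

    def __init__(self, pi, exch):
        self._build(np.asarray(pi, float), _exch_matrix(exch, 4))

    def with_rate(self, rho: float) -> "RateModel":
        """A copy of this model with every rate multiplied by rho."""
        m = RateModel(self.pi, self.exch * rho)
        # rebuild without re-normalizing: scale the generator directly
        m.Q = self.Q * rho
        m.exch = self.exch * rho
        m.scale = rho
        m._decompose()
        return m

    def encode(self, obs: str) -> int:
        return NUC_INDEX.get(obs, MISSING)

    def to_dict(self) -> dict:
        iu = np.triu_indices(4, k=1)
        return {
            "type": "gtr4",
            "pi": {c: float(p) for c, p in zip(NUC, self.pi)},
            "exch": {f"{NUC[i]}{NUC[j]}": float(self.exch[i, j]) for i, j in zip(*iu)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        pi = np.array([d["pi"][c] for c in NUC])
        exch = np.array([d["exch"][f"{NUC[i]}{NUC[j]}"] for i, j in EXCH_ORDER])
        return cls(pi, exch)


@dataclass(init=False)
class PairRateModel(_ReversibleModel):
    """16-state reversible model over ordered dinucleotides.

    Normalized to TWO expected single-nucleotide substitution events per unit
    time (one per pair member), so branch lengths keep their per-site meaning
    and the Kronecker-sum independence model factorizes exactly."""

    pi: np.ndarray
    exch: np.ndarray
    Q: np.ndarray
    independent: bool = False
    scale: float = 1.0

    alphabet = PAIR16
    state_index = PAIR16_INDEX

    def __init__(self, pi16, exch16, independent: bool = False):
        # zero exchangeabilities are allowed on 16 states (the exact
        # independence model has none between doubly-substituted states)
        self._build(
            np.asarray(pi16, float),
            _exch_matrix(exch16, 16, allow_zero=True),
            target_rate=2.0,
        )
        self.independent = independent

    def encode(self, obs: str) -> int:
        return PAIR16_INDEX.get(obs, MISSING)


def build_gtr(pi, exch) -> RateModel:
    """GTR model from stationary frequencies and 6 exchangeabilities,
    scaled to one expected substitution per unit time."""
    return RateModel(pi, exch)


def jukes_cantor() -> RateModel:
    return build_gtr(np.full(4, 0.25), np.ones(6))


DEFAULT_STACKING_BIAS = {"GC": 8.0, "CG": 8.0, "AU": 8.0, "UA": 8.0, "GU": 3.0, "UG": 3.0}


def build_pair_model(
    pi16=None,
    exch16=None,
    from_single: RateModel | None = None,
    stacking_bias: Mapping[str, float] | None = None,
) -> PairRateModel:
    """16-state model, either explicit or derived from a 4-state model.

    With ``from_single`` and no bias, the result is the independence model:
    Q16 is the Kronecker sum Q (+) Q and pi16 = pi (x) pi, so pair-column
    likelihoods factorize into the two single-column likelihoods. A
    ``stacking_bias`` reweights the stationary mass of canonical pairs
    (keeping the independence exchangeabilities), producing a reversible
    model that favours canonical base pairs.
    """
    if from_single is not None:
        single = from_single
        pi16 = np.kron(single.pi, single.pi)
        Q16 = np.kron(single.Q, np.eye(4)) + np.kron(np.eye(4), single.Q)
        # reversible => symmetric exchangeabilities R_ij = Q_ij / pi_j
        exch16 = Q16 / pi16[None, :]
        np.fill_diagonal(exch16, 0.0)
        exch16 = 0.5 * (exch16 + exch16.T)
        if stacking_bias is None:
            # exact Kronecker sum: zero rate for double substitutions, so
            # pair-column likelihoods factorize exactly
            return PairRateModel(pi16, exch16, independent=True)
        for pair, w in stacking_bias.items():
            if w <= 0:
                raise ValueError(f"stacking bias for {pair} must be positive")
            pi16 = pi16.copy()
            pi16[PAIR16_INDEX[pair]] *= w
        pi16 = pi16 / pi16.sum()
        return PairRateModel(pi16, _with_floor(exch16), independent=False)
    if pi16 is None or exch16 is None:
        raise ValueError("need either from_single or explicit (pi16, exch16)")
    return PairRateModel(pi16, exch16, independent=False)


def _with_floor(exch16: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """The Kronecker-sum exchangeabilities are zero between states differing
    in both positions; a tiny floor keeps the chain irreducible (double
    substitutions are possible, just rare)."""
    out = exch16.copy()
    off = ~np.eye(16, dtype=bool)
    out[off] = np.maximum(out[off], floor)
    return out


def default_pair_model(single: RateModel | None = None) -> PairRateModel:
    """Canonical-pair-biased 16-state default used by the scorer."""
    return build_pair_model(from_single=single or jukes_cantor(), stacking_bias=DEFAULT_STACKING_BIAS)


# ---------------------------------------------------------------------------
# Trees


class PhyloTree:
    """A rooted tree with branch lengths, flattened for fast pruning.

    Nodes are indexed 0..n-1 in postorder (root last). ``children[v]`` lists
    child indices and ``blen[v]`` is the length of the edge above v.
    """

    def __init__(self, children: list[list[int]], blen: np.ndarray, leaf_names: dict[str, int]):
        self.children = children
        self.blen = np.asarray(blen, dtype=float)
        self.leaf_names = leaf_names
        self.n_nodes = len(children)
        self.root = self.n_nodes - 1
        if np.any(self.blen[: self.root] < 0) or not np.all(np.isfinite(self.blen[: self.root])):
            raise ValueError("branch lengths must be finite and non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_names, key=self.leaf_names.get)

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        if hasattr(source, "read"):
            text = source.read()
        else:
            s = str(source)
            if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
                text = s
            else:
                with open(s) as fh:
                    text = fh.read()
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf name in tree: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        blen = np.zeros(len(nodes))
        leaf_names: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                children[i].append(index[id(ch)])
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    label = nd.taxon.label if nd.taxon else (nd.label or "internal node")
                    raise ValueError(f"missing branch length for {label}")
                blen[i] = float(nd.edge.length)
                if blen[i] < 0:
                    label = nd.taxon.label if nd.taxon else (nd.label or "internal node")
                    raise ValueError(f"negative branch length for {label}")
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unnamed leaf in tree")
                name = nd.taxon.label.replace(" ", "_")
                if name in leaf_names:
                    raise ValueError(f"duplicate leaf name {name!r}")
                leaf_names[name] = i
        return cls(children, blen, leaf_names)

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 1, -1, -1):
            for ch in self.children[v]:
                depth[ch] = depth[v] + self.blen[ch]
        return {name: float(depth[i]) for name, i in self.leaf_names.items()}


# ---------------------------------------------------------------------------
# Pruning


def encode_observations(
    tree: PhyloTree, columns: Sequence[Mapping[str, str]], model: _ReversibleModel
) -> np.ndarray:
    """Encode a list of per-leaf observation mappings into an int matrix of
    shape (n_leaves, n_columns); unknown symbols and gaps become missing."""
    names = tree.leaves
    obs = np.full((len(names), len(columns)), MISSING, dtype=np.int64)
    for k, colmap in enumerate(columns):
        for name, sym in colmap.items():
            if name not in tree.leaf_names:
                raise KeyError(f"leaf {name!r} not in tree")
            obs[names.index(name), k] = model.encode(sym)
    return obs


def column_likelihoods(tree: PhyloTree, obs: np.ndarray, model: _ReversibleModel) -> np.ndarray:
    """Felsenstein pruning, vectorized over columns.

    ``obs`` is (n_leaves, n_columns) of state indices in tree-leaf order
    (``tree.leaves``), with -1 for missing data (marginalized)."""
    n_states = model.n_states
    n_cols = obs.shape[1]
    if obs.shape[0] != tree.n_leaves:
        raise ValueError("observation matrix does not match tree leaf count")
    partial = np.ones((tree.n_nodes, n_cols, n_states))
    for row, name in enumerate(tree.leaves):
        node = tree.leaf_names[name]
        states = obs[row]
        seen = states >= 0
        partial[node][seen] = 0.0
        partial[node][seen, states[seen]] = 1.0
    for v in range(tree.n_nodes):
        if not tree.children[v]:
            continue
        acc = np.ones((n_cols, n_states))
        for ch in tree.children[v]:
            P = model.transition_matrix(float(tree.blen[ch]))
            acc *= partial[ch] @ P.T
        partial[v] = acc
    return partial[tree.root] @ model.pi


def column_likelihood(
    tree: PhyloTree, observations: Mapping[str, str], model: _ReversibleModel
) -> float:
    """P(column observations | tree, model); leaves absent from the mapping
    (or gapped) are marginalized as missing data."""
    obs = encode_observations(tree, [observations], model)
    return float(column_likelihoods(tree, obs, model)[0])


# ---------------------------------------------------------------------------
# Pairwise distances


def gtr_distance(seq1: str, seq2: str, model: RateModel, t_max: float = 20.0) -> float:
    """ML evolutionary distance (expected substitutions/site) between two
    sequences under a fixed GTR model; gapped columns are dropped."""
    pairs = [
        (NUC_INDEX[a], NUC_INDEX[b])
        for a, b in zip(seq1.upper().replace("T", "U"), seq2.upper().replace("T", "U"))
        if a in NUC_INDEX and b in NUC_INDEX
    ]
    if not pairs:
        raise ValueError("no comparable (ungapped) columns")
    counts = np.zeros((4, 4))
    for a, b in pairs:
        counts[a, b] += 1
    if counts.trace() == counts.sum():
        return 0.0

    log_pi = np.log(model.pi)

    def nll(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(np.maximum(P, 1e-300)))
        return -float(ll.sum())

    res = minimize_scalar(nll, bounds=(1e-6, t_max), method="bounded", options={"xatol": 1e-8})
    t_hat = float(res.x)
    if t_hat > t_max - 1e-3:
        warnings.warn("distance estimate saturated; reporting +inf")
        return float("inf")
    return t_hat


def estimate_gtr(columns, tree: PhyloTree, maxiter: int = 200) -> RateModel:
    """Fit a GTR model by maximizing the summed column log-likelihood.

    ``columns`` is either a list of {leaf: base} mappings or an int matrix
    (n_leaves, n_columns) in ``tree.leaves`` order. Stationary frequencies
    are initialized from empirical base counts.
    """
    if isinstance(columns, np.ndarray):
        obs = columns
    else:
        obs = encode_observations(tree, columns, jukes_cantor())
    counts = np.bincount(obs[obs >= 0], minlength=4).astype(float)
    if np.count_nonzero(counts) < 2:
        raise ValueError("monomorphic alignment: cannot fit substitution model")
    pi0 = (counts + 1.0) / (counts.sum() + 4.0)

    def unpack(theta):
        pi = np.exp(np.concatenate([theta[:3], [0.0]]))
        pi /= pi.sum()
        exch = np.exp(np.concatenate([theta[3:8], [0.0]]))
        return pi, exch

    def nll(theta):
        pi, exch = unpack(theta)
        try:
            model = RateModel(pi, exch)
        except ValueError:
            return 1e12
        lik = column_likelihoods(tree, obs, model)
        if np.any(lik <= 0):
            return 1e12
        return -float(np.log(lik).sum())

    theta0 = np.concatenate([np.log(pi0[:3] / pi0[3]), np.zeros(5)])
    start_nll = nll(np.zeros(8))  # JC starting point reference
    res = minimize(nll, theta0, method="Nelder-Mead", options={"maxiter": maxiter * 10, "xatol": 1e-5, "fatol": 1e-7})
    best = res.x if nll(res.x) <= start_nll else np.zeros(8)
    pi, exch = unpack(best)
    return RateModel(pi, exch)


# ---------------------------------------------------------------------------
# Simulation down a tree (shared by synth fixtures and the evolve-mode null)


def evolve_states(
    tree: PhyloTree, model: _ReversibleModel, n_columns: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw root states from the stationary distribution and evolve them down
    the tree; returns (n_leaves, n_columns) state indices in tree.leaves order."""
    states = np.empty((tree.n_nodes, n_columns), dtype=np.int64)
    states[tree.root] = rng.choice(model.n_states, size=n_columns, p=model.pi)
    for v in range(tree.n_nodes - 1, -1, -1):
        for ch in tree.children[v]:
            P = model.transition_matrix(float(tree.blen[ch]))
            u = rng.random(n_columns)
            cdf = np.cumsum(P, axis=1)
            states[ch] = (u[:, None] > cdf[states[v]]).sum(axis=1)
    return np.vstack([states[tree.leaf_names[name]] for name in tree.leaves])
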