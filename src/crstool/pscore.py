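"""Three-model phylogenetic ranking statistic for structure-annotated
alignments.

For every consensus base pair the 16-state structured model is compared (in
log2 units, i.e. bits) against two single-nucleotide alternatives: a conserved
unstructured model and a faster neutral/misaligned model. Pair contributions
are weighted by thermodynamic pair probabilities averaged over rows; the final
statistic is the minimum of the two total log-odds, so a structure must beat
BOTH alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crstool.io_formats import AnnotatedAlignment, structure_pairs
from crstool.phylo_models import (
    MISSING,
    PairRateModel,
    PhyloTree,
    RateModel,
    column_likelihoods,
    default_pair_model,
    jukes_cantor,
)
from crstool.thermo import DEFAULT_ENERGY_MODEL, EnergyModel, alignment_pair_weights

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class ConsensusStructure:
    """Pairs P (1-based columns, i<j, non-crossing) and unpaired columns U."""

    pairs: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...]
    length: int

    def __post_init__(self) -> None:
        cols = {c for ij in self.pairs for c in ij}
        if cols & set(self.unpaired):
            raise ValueError("columns cannot be both paired and unpaired")
        if len(cols) + len(self.unpaired) != self.length:
            raise ValueError("pairs and unpaired columns must partition 1..L")


def parse_structure(dotbracket: str, h: int = 3) -> ConsensusStructure:
    """Parse a dot-bracket string; pairs enclosing <= h columns are rejected."""
    pairs = structure_pairs(dotbracket, h=h)
    paired_cols = {c for ij in pairs for c in ij}
    unpaired = tuple(c for c in range(1, len(dotbracket) + 1) if c not in paired_cols)
    return ConsensusStructure(pairs=tuple(pairs), unpaired=unpaired, length=len(dotbracket))


@dataclass
class ScoreModels:
    """The three scoring models. ``neut`` is typically ``cons`` with every
    rate multiplied by rho > 1 (poorly conserved / misaligned background)."""

    pair: PairRateModel
    cons: RateModel
    neut: RateModel

    @classmethod
    def default(cls, rho: float = 4.0) -> "ScoreModels":
        cons = jukes_cantor()
        return cls(pair=default_pair_model(cons), cons=cons, neut=cons.with_rate(rho))

    @classmethod
    def from_config(cls, cfg: dict) -> "ScoreModels":
        """Build the three models from a plain mapping (e.g. parsed YAML):
        keys ``pi`` ({A,C,G,U}: freq), ``exch`` ({AC,AG,AU,CG,CU,GU}: rate),
        ``rho`` (neutral rate multiplier) and ``stacking_bias``."""
        from crstool.phylo_models import (
            DEFAULT_STACKING_BIAS,
            NUC,
            EXCH_ORDER,
            build_gtr,
            build_pair_model,
        )
        import numpy as _np

        if "pi" in cfg or "exch" in cfg:
            pi = _np.array([cfg.get("pi", {}).get(c, 0.25) for c in NUC])
            exch_map = cfg.get("exch", {})
            exch = _np.array(
                [exch_map.get(f"{NUC[i]}{NUC[j]}", 1.0) for i, j in EXCH_ORDER]
            )
            cons = build_gtr(pi / pi.sum(), exch)
        else:
            cons = jukes_cantor()
        bias = cfg.get("stacking_bias", DEFAULT_STACKING_BIAS)
        pair = build_pair_model(from_single=cons, stacking_bias=bias)
        rho = float(cfg.get("rho", 4.0))
        if rho <= 1.0:
            raise ValueError("neutral rate multiplier rho must exceed 1")
        return cls(pair=pair, cons=cons, neut=cons.with_rate(rho))


@dataclass
class PairContribution:
    i: int
    j: int
    weight: float
    l_pair: float
    l_cons_i: float
    l_cons_j: float
    l_neut_i: float
    l_neut_j: float

    @property
    def cons_gain(self) -> float:
        return self.l_pair - self.l_cons_i - self.l_cons_j

    @property
    def neut_gain(self) -> float:
        return self.l_pair - self.l_neut_i - self.l_neut_j


@dataclass
class PscoreResult:
    per_pair: list[PairContribution]
    delta_cons: float
    delta_neut: float
    pscore: float
    n_pairs: int
    n_unpaired: int
    id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.pscore):
            raise ValueError("pscore must be finite")


def _encode_columns(aln: AnnotatedAlignment, tree: PhyloTree) -> np.ndarray:
    """(n_tree_leaves, L) single-base state matrix; gaps/unknowns missing."""
    names = tree.leaves
    L = aln.length
    obs = np.full((len(names), L), MISSING, dtype=np.int64)
    row_by_name = dict(aln.rows)
    from crstool.phylo_models import NUC_INDEX

    for r, name in enumerate(names):
        seq = row_by_name.get(name)
        if seq is None:
            continue
        for c, ch in enumerate(seq):
            obs[r, c] = NUC_INDEX.get(ch, MISSING)
    unmatched = [n for n in aln.names if n not in tree.leaf_names]
    if unmatched:
        raise KeyError(f"alignment rows not in tree: {unmatched}")
    return obs


def _pair_observations(obs: np.ndarray, pairs) -> np.ndarray:
    """Combine single-base states at columns (i,j) into 16-state indices;
    a gap at either column makes the whole pair observation missing."""
    out = np.full((obs.shape[0], len(pairs)), MISSING, dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        a = obs[:, i - 1]
        b = obs[:, j - 1]
        ok = (a >= 0) & (b >= 0)
        out[ok, k] = a[ok] * 4 + b[ok]
    return out


def pair_log_odds(
    tree: PhyloTree, aln: AnnotatedAlignment, i: int, j: int, models: ScoreModels
) -> tuple[float, float, float]:
    """(l_pair, l_cons_i + l_cons_j, l_neut_i + l_neut_j) in bits for one
    column pair."""
    obs = _encode_columns(aln, tree)
    pair_obs = _pair_observations(obs, [(i, j)])
    l_pair = np.log(column_likelihoods(tree, pair_obs, models.pair))[0] / LOG2
    single = obs[:, [i - 1, j - 1]]
    l_cons = np.log(column_likelihoods(tree, single, models.cons)) / LOG2
    l_neut = np.log(column_likelihoods(tree, single, models.neut)) / LOG2
    return float(l_pair), float(l_cons.sum()), float(l_neut.sum())


def pscore(
    aln: AnnotatedAlignment,
    structure: ConsensusStructure | str,
    tree: PhyloTree,
    models: ScoreModels | None = None,
    em: EnergyModel = DEFAULT_ENERGY_MODEL,
    gap_cap: float = 0.5,
    unit_weights: bool = False,
) -> PscoreResult:
    """Score an annotated alignment.

    delta_cons = sum over pairs of w_ij * (l_pair - l_cons_i - l_cons_j);
    delta_neut adds the unpaired-column log-odds cons vs neut; the pscore is
    min(delta_cons, delta_neut) in bits. Pairs with a gapped-row fraction
    above ``gap_cap`` get weight zero. ``unit_weights`` disables the
    thermodynamic weighting (w_ij = 1 for pairs under the gap cap).
    """
    if models is None:
        models = ScoreModels.default()
    if isinstance(structure, str):
        structure = parse_structure(structure, h=em.h)
    if structure.length != aln.length:
        raise ValueError(
            f"structure length {structure.length} != alignment length {aln.length}"
        )
    obs = _encode_columns(aln, tree)
    L = aln.length
    l_cons = np.log(column_likelihoods(tree, obs, models.cons)) / LOG2
    l_neut = np.log(column_likelihoods(tree, obs, models.neut)) / LOG2

    pairs = list(structure.pairs)
    per_pair: list[PairContribution] = []
    delta_cons = 0.0
    delta_neut = 0.0
    if pairs:
        pair_obs = _pair_observations(obs, pairs)
        l_pairs = np.log(column_likelihoods(tree, pair_obs, models.pair)) / LOG2
        if unit_weights:
            weights = np.ones(len(pairs))
        else:
            weights = alignment_pair_weights(aln, pairs, em)
        n_rows = len(aln.rows)
        seqs = aln.sequences
        for k, (i, j) in enumerate(pairs):
            gap_frac = sum(
                1 for s in seqs if s[i - 1] == "-" or s[j - 1] == "-"
            ) / n_rows
            w = 0.0 if gap_frac > gap_cap else float(weights[k])
            contrib = PairContribution(
                i=i,
                j=j,
                weight=w,
                l_pair=float(l_pairs[k]),
                l_cons_i=float(l_cons[i - 1]),
                l_cons_j=float(l_cons[j - 1]),
                l_neut_i=float(l_neut[i - 1]),
                l_neut_j=float(l_neut[j - 1]),
            )
            per_pair.append(contrib)
            delta_cons += w * contrib.cons_gain
            delta_neut += w * contrib.neut_gain
    for c in structure.unpaired:
        delta_neut += float(l_cons[c - 1] - l_neut[c - 1])

    return PscoreResult(
        per_pair=per_pair,
        delta_cons=float(delta_cons),
        delta_neut=float(delta_neut),
        pscore=float(min(delta_cons, delta_neut)),
        n_pairs=len(pairs),
        n_unpaired=len(structure.unpaired),
        id=aln.id,
    )


def classify(result: PscoreResult, threshold: float) -> bool:
    """Call a structure at the closed inequality pscore >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return result.pscore >= threshold
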