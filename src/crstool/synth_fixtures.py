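"""Seeded generators for pipeline-shaped synthetic inputs.

Everything here is a pure function of its configuration (seed included):
structured alignments evolved on a tree with compensatory change at paired
columns, negative-binomial count matrices, and probing count tables matching
a known structure. Truth labels travel with each artifact so downstream ROC
and concordance statistics need no external annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crstool.expression_probing import CountMatrix
from crstool.io_formats import AnnotatedAlignment, GenomeWindows
from crstool.phylo_models import (
    CANONICAL_PAIRS,
    NUC,
    PAIR16_INDEX,
    PairRateModel,
    PhyloTree,
    RateModel,
    default_pair_model,
    evolve_states,
    jukes_cantor,
)
from crstool.pscore import ConsensusStructure, parse_structure


@dataclass
class SimulationConfig:
    tree: PhyloTree
    structure: ConsensusStructure
    pair_model: PairRateModel | None = None
    single_model: RateModel | None = None
    compensatory_rate: float = 1.0
    nb_mean: float = 50.0
    nb_dispersion: float = 0.3
    probing_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.compensatory_rate, self.probing_noise):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.single_model is None:
            self.single_model = jukes_cantor()
        if self.pair_model is None:
            self.pair_model = compensatory_pair_model(self.single_model, self.compensatory_rate)


def compensatory_pair_model(single: RateModel, compensatory_rate: float) -> PairRateModel:
    """Canonical-pair-biased 16-state model whose within-canonical exchange
    rates are scaled by ``compensatory_rate`` (0 freezes compensatory
    double substitutions, 1 keeps the default intensity)."""
    base = default_pair_model(single)
    exch = base.exch.copy()
    canon = [PAIR16_INDEX[p] for p in CANONICAL_PAIRS]
    scale = max(compensatory_rate, 1e-3)
    for a in canon:
        for b in canon:
            if a != b:
                exch[a, b] *= 10.0 * scale
    return PairRateModel(base.pi, exch, independent=False)


def random_hairpin_structure(length: int, stem: int, h: int = 3) -> ConsensusStructure:
    """A single hairpin of ``stem`` pairs centred in ``length`` columns."""
    loop = length - 2 * stem
    if loop <= h:
        raise ValueError("structure does not fit: loop would violate hairpin minimum")
    db = "(" * stem + "." * loop + ")" * stem
    return parse_structure(db, h=h)


def structure_to_dotbracket(structure: ConsensusStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def simulate_structured_alignment(cfg: SimulationConfig) -> AnnotatedAlignment:
    """Evolve an alignment on cfg.tree: paired columns jointly under the
    16-state model, unpaired columns under the 4-state model."""
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree
    structure = cfg.structure
    L = structure.length
    names = tree.leaves
    chars = np.empty((len(names), L), dtype="<U1")

    if structure.unpaired:
        single_states = evolve_states(tree, cfg.single_model, len(structure.unpaired), rng)
        for k, col in enumerate(structure.unpaired):
            for r in range(len(names)):
                chars[r, col - 1] = NUC[single_states[r, k]]
    if structure.pairs:
        pair_states = evolve_states(tree, cfg.pair_model, len(structure.pairs), rng)
        for k, (i, j) in enumerate(structure.pairs):
            for r in range(len(names)):
                s = pair_states[r, k]
                chars[r, i - 1] = NUC[s // 4]
                chars[r, j - 1] = NUC[s % 4]

    rows = [(name, "".join(chars[r])) for r, name in enumerate(names)]
    return AnnotatedAlignment(
        rows=rows, structure=structure_to_dotbracket(structure), id=f"synth-{cfg.seed}"
    )


def simulate_read_counts(
    windows: GenomeWindows | int,
    cfg: SimulationConfig,
    n_samples: int = 4,
    sample_factors=None,
) -> CountMatrix:
    """Negative-binomial window x sample counts with per-sample scale factors.

    Mean of window w, sample s is nb_mean * factor_s; NB size parameter is
    1 / nb_dispersion (variance = m + dispersion * m^2)."""
    if cfg.nb_mean <= 0 or cfg.nb_dispersion <= 0:
        raise ValueError("nb_mean and nb_dispersion must be positive")
    n_windows = windows if isinstance(windows, int) else len(windows.intervals)
    factors = np.ones(n_samples) if sample_factors is None else np.asarray(sample_factors, float)
    if factors.size != n_samples or np.any(factors <= 0):
        raise ValueError("need one positive scale factor per sample")
    rng = np.random.default_rng(cfg.seed)
    size = 1.0 / cfg.nb_dispersion
    mean = cfg.nb_mean * factors[None, :] * np.ones((n_windows, 1))
    p = size / (size + mean)
    return CountMatrix(counts=rng.negative_binomial(size, p))


def simulate_probing_counts(
    structure: ConsensusStructure,
    length: int,
    depth: float = 100.0,
    probing_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(native, denatured) count vectors so the lfc > 1 pairing rule fires at
    paired positions with probability 1 - probing_noise and at unpaired
    positions with probability probing_noise."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= probing_noise <= 1.0:
        raise ValueError("probing_noise must lie in [0,1]")
    rng = np.random.default_rng(seed)
    paired = np.zeros(length, dtype=bool)
    for i, j in structure.pairs:
        paired[i - 1] = paired[j - 1] = True
    flip = rng.random(length) < probing_noise
    signal = paired ^ flip  # positions that should be CALLED paired
    native = np.empty(length)
    denatured = np.empty(length)
    # paired signal: denatured >> native (termination when denatured);
    # unpaired: comparable counts, lfc ~ 0.
    hi = rng.poisson(depth, size=length) + depth
    lo = rng.poisson(depth * 0.1, size=length)
    mid = rng.poisson(depth * 0.5, size=length)
    native = np.where(signal, lo, mid).astype(float)
    denatured = np.where(signal, hi, mid).astype(float)
    return native, denatured
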