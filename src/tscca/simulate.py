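"""Synthetic benchmark: planted-module tensors and tri-cluster metrics.

The default configuration reproduces the published simulation protocol:
a 300 × 30 × 4 "correlation" tensor with background noise N(0, 0.2²)
and three planted 100-gene × 10-miRNA blocks, each appearing in two of
the first three cancer slices with opposite signs (mean ±0.5, sd 0.2);
slice 4 is pure noise.  Because each block is a constant-mean patch
replicated (with a sign flip) across its two slices, every planted
module is a sparse rank-1 signal the tensor model can represent, with
the sign absorbed into the cancer weights.

Recovered modules are scored against the planted truth with the two
standard tri-clustering metrics on (gene, miRNA, cancer) cell sets:
Recovery (mean over true modules of the best Jaccard index against any
prediction; higher is better) and CE (clustering error: one minus the
optimally matched overlap divided by the union of all cells; lower is
better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ParameterError, ValidationError
from .tensor import CorrelationTensor, ExpressionMatrix

__all__ = [
    "PlantedBlock",
    "SimulationConfig",
    "PlantedTruth",
    "paper_default_config",
    "generate_tensor",
    "shuffle_tensor",
    "unshuffle_tensor",
    "generate_expression",
    "recovery_score",
    "ce_score",
]


@dataclass(frozen=True)
class PlantedBlock:
    """One planted patch: half-open gene/miRNA ranges, signed mean per slice."""

    genes: tuple[int, int]
    mirnas: tuple[int, int]
    slice_means: dict[int, float]  # cancer index -> block mean
    sd: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Dimensions, planted blocks and background noise of one synthetic tensor."""

    p: int = 300
    q: int = 30
    M: int = 4
    blocks: tuple[PlantedBlock, ...] = ()
    noise_sd: float = 0.2
    clip: bool = False
    allow_overlap: bool = False

    def validate(self) -> None:
        if min(self.p, self.q, self.M) < 1:
            raise ParameterError("dimensions must be positive")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        covered: dict[int, list[tuple[range, range]]] = {}
        for b in self.blocks:
            g0, g1 = b.genes
            m0, m1 = b.mirnas
            if not (0 <= g0 < g1 <= self.p and 0 <= m0 < m1 <= self.q):
                raise ParameterError(f"block ranges {b.genes}/{b.mirnas} out of bounds")
            if b.sd < 0:
                raise ParameterError("block sd must be >= 0")
            for k in b.slice_means:
                if not 0 <= k < self.M:
                    raise ParameterError(f"slice index {k} out of bounds")
                if not self.allow_overlap:
                    for gr, mr in covered.get(k, []):
                        if g0 < gr.stop and gr.start < g1 and \
                           m0 < mr.stop and mr.start < m1:
                            raise ParameterError(
                                f"overlapping blocks on slice {k}; pass "
                                f"allow_overlap=True to permit this"
                            )
                covered.setdefault(k, []).append((range(g0, g1), range(m0, m1)))


@dataclass
class PlantedTruth:
    """Index sets of the planted modules, tracked through any shuffling."""

    modules: list[tuple[set[int], set[int], set[int]]]
    gene_perm: np.ndarray | None = None
    mirna_perm: np.ndarray | None = None

    def cells(self, which: int) -> set[tuple[int, int, int]]:
        I, J, K = self.modules[which]
        return {(i, j, k) for i in I for j in J for k in K}


def paper_default_config(noise_sd: float = 0.2, sd: float = 0.2,
                         clip: bool = False) -> SimulationConfig:
    """The published 300 × 30 × 4 protocol with three sign-opposite blocks."""
    blocks = (
        PlantedBlock((0, 100), (0, 10), {0: 0.5, 1: -0.5}, sd=sd),
        PlantedBlock((100, 200), (10, 20), {0: -0.5, 2: 0.5}, sd=sd),
        PlantedBlock((200, 300), (20, 30), {1: 0.5, 2: -0.5}, sd=sd),
    )
    return SimulationConfig(p=300, q=30, M=4, blocks=blocks,
                            noise_sd=noise_sd, clip=clip)


def generate_tensor(config: SimulationConfig, seed: int,
                    ) -> tuple[CorrelationTensor, PlantedTruth]:
    """Draw one synthetic tensor with planted blocks.

    Background entries are N(0, noise_sd²); each block overwrites its
    patch with N(mean, sd²) draws per slice.  Entries are left unclipped
    by default (matching the stated normal distributions exactly), so
    the tensor is flagged ``built_from_data=False`` unless clipping to
    [-1, 1] is requested.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    T = rng.normal(0.0, config.noise_sd, size=(config.p, config.q, config.M))
    truth_modules: list[tuple[set[int], set[int], set[int]]] = []
    for b in config.blocks:
        g0, g1 = b.genes
        m0, m1 = b.mirnas
        for k, mean in b.slice_means.items():
            shape = (g1 - g0, m1 - m0)
            patch = (np.full(shape, mean) if b.sd == 0
                     else rng.normal(mean, b.sd, size=shape))
            T[g0:g1, m0:m1, k] = patch
        truth_modules.append(
            (set(range(g0, g1)), set(range(m0, m1)), set(b.slice_means))
        )
    if config.clip:
        np.clip(T, -1.0, 1.0, out=T)
    tensor = CorrelationTensor(
        T,
        [f"g{i}" for i in range(config.p)],
        [f"m{j}" for j in range(config.q)],
        [f"c{k}" for k in range(config.M)],
        built_from_data=config.clip,
    )
    return tensor, PlantedTruth(truth_modules)


def shuffle_tensor(tensor: CorrelationTensor, truth: PlantedTruth, seed: int,
                   ) -> tuple[CorrelationTensor, PlantedTruth]:
    """Randomly permute genes and miRNAs consistently across all slices.

    The same permutations are applied to the recorded truth, so planted
    modules remain identifiable after shuffling; the permutations are
    stored on the returned truth for exact inversion.
    """
    rng = np.random.default_rng(seed)
    p, q, _ = tensor.shape
    gperm = rng.permutation(p)  # gperm[new] = old
    mperm = rng.permutation(q)
    values = tensor.values[np.ix_(gperm, mperm)]
    gene_ids = [tensor.gene_ids[i] for i in gperm]
    mirna_ids = [tensor.mirna_ids[j] for j in mperm]
    ginv = np.argsort(gperm)  # old -> new
    minv = np.argsort(mperm)
    modules = [
        ({int(ginv[i]) for i in I}, {int(minv[j]) for j in J}, set(K))
        for I, J, K in truth.modules
    ]
    shuffled = CorrelationTensor(
        values, gene_ids, mirna_ids, list(tensor.cancer_ids),
        sample_counts=tensor.sample_counts,
        built_from_data=tensor.built_from_data,
    )
    return shuffled, PlantedTruth(modules, gene_perm=gperm, mirna_perm=mperm)


def unshuffle_tensor(tensor: CorrelationTensor, truth: PlantedTruth,
                     ) -> CorrelationTensor:
    """Invert :func:`shuffle_tensor` using the stored permutations."""
    if truth.gene_perm is None or truth.mirna_perm is None:
        raise ValidationError("truth carries no stored permutations")
    ginv = np.argsort(truth.gene_perm)
    minv = np.argsort(truth.mirna_perm)
    values = tensor.values[np.ix_(ginv, minv)]
    gene_ids = [tensor.gene_ids[i] for i in ginv]
    mirna_ids = [tensor.mirna_ids[j] for j in minv]
    return CorrelationTensor(
        values, gene_ids, mirna_ids, list(tensor.cancer_ids),
        sample_counts=tensor.sample_counts,
        built_from_data=tensor.built_from_data,
    )


def generate_expression(config: SimulationConfig, samples: int, seed: int,
                        ) -> tuple[list[tuple[str, ExpressionMatrix, ExpressionMatrix]],
                                   PlantedTruth]:
    """Matched per-cancer expression whose correlation tensor carries the blocks.

    For each planted block and each of its cancers, a latent standard-
    normal factor per sample is mixed into the block's genes and miRNAs
    with loadings chosen so each gene-miRNA pair has population
    correlation equal to the block mean (sign included); all other
    coordinates are independent noise.  With rho the target mean, gene
    columns are sqrt(|rho|)·f + sqrt(1-|rho|)·eps and miRNA columns use
    the sign-carrying loading, giving corr = rho exactly in population.
    """
    config.validate()
    if samples < 10:
        raise ParameterError("need >= 10 samples per cancer")
    for b in config.blocks:
        for mean in b.slice_means.values():
            if abs(mean) >= 1:
                raise ParameterError(f"target correlation {mean} infeasible (|mean| >= 1)")
    rng = np.random.default_rng(seed)
    pairs = []
    truth_modules = [
        (set(range(*b.genes)), set(range(*b.mirnas)), set(b.slice_means))
        for b in config.blocks
    ]
    for k in range(config.M):
        X = rng.standard_normal((samples, config.p))
        Y = rng.standard_normal((samples, config.q))
        for b in config.blocks:
            if k not in b.slice_means:
                continue
            rho = b.slice_means[k]
            a = np.sqrt(abs(rho))
            c = np.sqrt(1 - abs(rho))
            f = rng.standard_normal(samples)
            g0, g1 = b.genes
            m0, m1 = b.mirnas
            X[:, g0:g1] = a * f[:, None] + c * X[:, g0:g1]
            Y[:, m0:m1] = np.sign(rho) * a * f[:, None] + c * Y[:, m0:m1]
        cid = f"c{k}"
        pairs.append((
            cid,
            ExpressionMatrix(X, [f"{cid}_s{t}" for t in range(samples)],
                             [f"g{i}" for i in range(config.p)]),
            ExpressionMatrix(Y, [f"{cid}_s{t}" for t in range(samples)],
                             [f"m{j}" for j in range(config.q)]),
        ))
    return pairs, PlantedTruth(truth_modules)


def _as_cells(module) -> set[tuple[int, int, int]]:
    if isinstance(module, set):
        return module
    if isinstance(module, tuple) and len(module) == 3:
        I, J, K = module
        return {(i, j, k) for i in I for j in J for k in K}
    return module.cells()  # core.Module


def recovery_score(truth, predicted) -> float:
    """Mean over true modules of the best Jaccard index against any prediction.

    Modules may be given as cell sets, (I, J, K) index-set triples, or
    fitted Module objects.  1.0 means every true module is matched
    exactly by some prediction; in [0, 1].
    """
    t_cells = [_as_cells(t) for t in _truth_list(truth)]
    p_cells = [_as_cells(p) for p in predicted]
    if not t_cells:
        raise ValidationError("empty truth")
    if not p_cells:
        return 0.0
    scores = []
    for t in t_cells:
        best = max(len(t & p) / len(t | p) if (t or p) else 0.0 for p in p_cells)
        scores.append(best)
    return float(np.mean(scores))


def ce_score(truth, predicted) -> float:
    """Clustering error: 1 − matched overlap / |union of all cells|.

    The overlap is the total weight of a maximum one-to-one matching
    between true and predicted modules, where a pair's weight is the
    number of shared cells.  0 means a perfect reconstruction; lower
    is better.
    """
    t_cells = [_as_cells(t) for t in _truth_list(truth)]
    p_cells = [_as_cells(p) for p in predicted]
    if not t_cells:
        raise ValidationError("empty truth")
    universe: set[tuple[int, int, int]] = set()
    for s in t_cells + p_cells:
        universe |= s
    if not universe:
        return 0.0
    if not p_cells:
        return 1.0
    W = np.zeros((len(t_cells), len(p_cells)))
    for a, t in enumerate(t_cells):
        for b, p in enumerate(p_cells):
            W[a, b] = len(t & p)
    rows, cols = linear_sum_assignment(-W)
    matched = W[rows, cols].sum()
    return float(1.0 - matched / len(universe))


def _truth_list(truth):
    if isinstance(truth, PlantedTruth):
        return truth.modules
    return list(truth)
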