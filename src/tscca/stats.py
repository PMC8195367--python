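"""Modularity scoring and permutation-null statistics on modules.

A module's modularity is the mean absolute correlation over its
gene × miRNA × cancer sub-tensor — high when the selected genes and
miRNAs are strongly co-expressed across the selected cancers.  Its
significance is judged against size-matched random modules drawn
uniformly from the tensor axes; permutation p-values use the add-one
estimator (1 + #{null >= observed}) / (1 + n_perm), which can never
be zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .tensor import CorrelationTensor, ExpressionMatrix

__all__ = [
    "ModularityResult",
    "OverlapTestResult",
    "modularity",
    "basic_modularity",
    "permutation_test_modularity",
    "coexpression_modularity",
    "permutation_test_coexpression",
    "module_overlap_test",
    "bonferroni_threshold",
]


@dataclass
class ModularityResult:
    score: float
    null_scores: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class OverlapTestResult:
    module_a: str
    module_b: str
    observed_overlap: int
    per_axis_overlap: tuple[int, int, int]
    p_value: float
    significant: bool
    n_perm: int
    seed: int


def _perm_p(null: np.ndarray, observed: float) -> float:
    return (1 + int(np.sum(null >= observed))) / (1 + null.size)


def _as_index(sel, n: int, what: str) -> np.ndarray:
    idx = np.asarray(sorted(sel), dtype=int)
    if idx.size == 0:
        raise ValidationError(f"empty {what} index set")
    if idx.min() < 0 or idx.max() >= n:
        raise ValidationError(f"{what} indices out of bounds [0, {n})")
    return idx


def modularity(C: CorrelationTensor | np.ndarray, I, J, K) -> float:
    """Mean |C_ijk| over the sub-tensor I × J × K (all sets nonempty)."""
    T = C.values if isinstance(C, CorrelationTensor) else np.asarray(C, dtype=float)
    I = _as_index(I, T.shape[0], "gene")
    J = _as_index(J, T.shape[1], "miRNA")
    K = _as_index(K, T.shape[2], "cancer")
    return float(np.mean(np.abs(T[np.ix_(I, J, K)])))


def basic_modularity(C: CorrelationTensor, cancer) -> float:
    """Whole-slice modularity: all genes × all miRNAs for one cancer.

    The per-cancer baseline a module's score is compared against.
    ``cancer`` may be an index or a cancer id.
    """
    if isinstance(cancer, str):
        try:
            cancer = C.cancer_ids.index(cancer)
        except ValueError:
            raise ValidationError(f"unknown cancer id {cancer!r}") from None
    p, q, M = C.shape
    if not 0 <= cancer < M:
        raise ValidationError(f"cancer index {cancer} out of bounds")
    return float(np.mean(np.abs(C.values[:, :, cancer])))


def permutation_test_modularity(C: CorrelationTensor | np.ndarray, module,
                                n_perm: int = 1000, seed: int = 0,
                                ) -> ModularityResult:
    """Compare a module's modularity to size-matched random modules.

    Null modules draw |I| genes, |J| miRNAs and |K| cancers uniformly
    without replacement from the full axes.  ``module`` is either a
    fitted Module or an (I, J, K) triple.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    T = C.values if isinstance(C, CorrelationTensor) else np.asarray(C, dtype=float)
    I, J, K = module.supports() if hasattr(module, "supports") else module
    p, q, M = T.shape
    nI, nJ, nK = len(I), len(J), len(K)
    if nI > p or nJ > q or nK > M:
        raise ValidationError("module larger than a tensor axis")
    observed = modularity(T, I, J, K)
    rng = np.random.default_rng(seed)
    absT = np.abs(T)
    null = np.empty(n_perm)
    for b in range(n_perm):
        ri = rng.choice(p, size=nI, replace=False)
        rj = rng.choice(q, size=nJ, replace=False)
        rk = rng.choice(M, size=nK, replace=False)
        null[b] = absT[np.ix_(ri, rj, rk)].mean()
    return ModularityResult(score=observed, null_scores=null,
                            p_value=_perm_p(null, observed),
                            n_perm=n_perm, seed=seed)


def coexpression_modularity(E: ExpressionMatrix, features) -> float:
    """Mean |pairwise Pearson correlation| within a feature subset.

    The gene/miRNA cooperativity score: average absolute correlation
    over all unordered distinct pairs (diagonal excluded).  E must be
    standardized; the subset needs at least 2 features.
    """
    if not E.standardized:
        raise ValidationError("expression must be standardized")
    idx = [E.feature_ids.index(f) if isinstance(f, str) else int(f)
           for f in features]
    if len(idx) < 2:
        raise ValidationError("need at least 2 features")
    if len(set(idx)) != len(idx):
        raise ValidationError("duplicate features in subset")
    sub = E.values[:, idx]
    n = sub.shape[0]
    R = sub.T @ sub / (n - 1)
    np.clip(R, -1.0, 1.0, out=R)
    iu = np.triu_indices(len(idx), k=1)
    return float(np.mean(np.abs(R[iu])))


def permutation_test_coexpression(E: ExpressionMatrix, features,
                                  n_perm: int = 1000, seed: int = 0,
                                  ) -> ModularityResult:
    """Null for :func:`coexpression_modularity`: resample equally many features."""
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    idx = [E.feature_ids.index(f) if isinstance(f, str) else int(f)
           for f in features]
    observed = coexpression_modularity(E, idx)
    rng = np.random.default_rng(seed)
    n_feat = E.n_features
    null = np.empty(n_perm)
    for b in range(n_perm):
        sel = rng.choice(n_feat, size=len(idx), replace=False)
        null[b] = coexpression_modularity(E, sel.tolist())
    return ModularityResult(score=observed, null_scores=null,
                            p_value=_perm_p(null, observed),
                            n_perm=n_perm, seed=seed)


def module_overlap_test(module_a, module_b, axis_sizes: tuple[int, int, int],
                        n_perm: int = 1000, seed: int = 0,
                        alpha: float = 0.05,
                        labels: tuple[str, str] = ("a", "b"),
                        ) -> OverlapTestResult:
    """Test whether two modules share more elements than chance.

    The statistic pools the three axes: |I_a∩I_b| + |J_a∩J_b| +
    |K_a∩K_b| (per-axis counts are also reported).  The null resamples
    both modules' supports independently and uniformly with sizes
    fixed; right-tail add-one p.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    sup_a = module_a.supports() if hasattr(module_a, "supports") else module_a
    sup_b = module_b.supports() if hasattr(module_b, "supports") else module_b
    p, q, M = axis_sizes
    sets_a = [set(map(int, s)) for s in sup_a]
    sets_b = [set(map(int, s)) for s in sup_b]
    for sa, sb, n, what in zip(sets_a, sets_b, (p, q, M),
                               ("gene", "miRNA", "cancer")):
        for s in (sa, sb):
            if s and (min(s) < 0 or max(s) >= n):
                raise ValidationError(f"{what} support outside universe of size {n}")
    per_axis = tuple(len(sa & sb) for sa, sb in zip(sets_a, sets_b))
    observed = sum(per_axis)
    rng = np.random.default_rng(seed)
    sizes_a = [len(s) for s in sets_a]
    sizes_b = [len(s) for s in sets_b]
    null = np.empty(n_perm)
    for b in range(n_perm):
        tot = 0
        for n, na, nb in zip((p, q, M), sizes_a, sizes_b):
            ra = rng.choice(n, size=na, replace=False)
            rb = rng.choice(n, size=nb, replace=False)
            tot += np.intersect1d(ra, rb, assume_unique=True).size
        null[b] = tot
    pv = _perm_p(null, observed)
    return OverlapTestResult(
        module_a=labels[0], module_b=labels[1], observed_overlap=observed,
        per_axis_overlap=per_axis, p_value=pv, significant=pv < alpha,
        n_perm=n_perm, seed=seed,
    )


def bonferroni_threshold(alpha: float = 0.05, family_size: int = 50) -> float:
    """Family-wise significance cut-off alpha / m for m modules tested."""
    if family_size < 1:
        raise ParameterError("family_size must be >= 1")
    return alpha / family_size
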