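"""Prognostic scoring of modules: PC1 summarization, median-split
log-rank tests, and Benjamini-Hochberg correction across module-cancer
pairs.

For each module and each cancer in its support, the joint expression of
the module's genes and miRNAs is summarized by its first principal
component; samples are split at the median score and the two groups are
compared with the standard two-group log-rank test.  The per-miRNA
variant uses each miRNA's own expression as the score.  All p-values
from one screen form a single BH family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ParameterError, ValidationError
from .io import SurvivalTable
from .tensor import ExpressionMatrix

__all__ = [
    "SurvivalAssociation",
    "module_pc1",
    "median_split_logrank",
    "bh_adjust",
    "survival_screen",
    "significant_pairs",
]


@dataclass
class SurvivalAssociation:
    module_id: str
    cancer_id: str
    statistic: float
    p_value: float
    adjusted_p: float
    group_sizes: tuple[int, int]
    score_id: str = ""  # miRNA id for the per-miRNA screen


def module_pc1(E: ExpressionMatrix) -> np.ndarray:
    """Per-sample scores on the leading principal component.

    E holds the module's genes and miRNAs as columns (standardized).
    Scores are the projections of rows onto the leading eigenvector of
    the feature covariance; the sign is fixed so the largest-magnitude
    loading is positive (the downstream median split is sign-invariant
    anyway).
    """
    if E.n_features < 2:
        raise ValidationError("PC1 needs at least 2 features")
    if E.n_samples < 3:
        raise ValidationError("PC1 needs at least 3 samples")
    if not E.standardized:
        raise ValidationError("expression must be standardized")
    X = E.values
    cov = X.T @ X / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    lead = vecs[:, -1]
    if vals[-1] <= 0:
        raise ComputationError("rank-0 input: leading eigenvalue is zero")
    j = int(np.argmax(np.abs(lead)))
    if lead[j] < 0:
        lead = -lead
    return X @ lead


def median_split_logrank(scores, sample_ids, table: SurvivalTable,
                         module_id: str = "", cancer_id: str = "",
                         score_id: str = "") -> SurvivalAssociation:
    """Two-group log-rank test after splitting samples at the median score.

    Samples at or below the median go to the low group.  Samples
    without a survival record (or vice versa) are dropped with a
    warning.  The returned association carries the chi-square statistic
    and its 1-df p-value; ``adjusted_p`` is filled by the screen.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(sample_ids):
        raise ValidationError("scores and sample_ids length mismatch")
    surv = {sid: (t, e) for sid, t, e in table.records}
    keep = [i for i, sid in enumerate(sample_ids) if sid in surv]
    dropped = scores.size - len(keep)
    if dropped:
        warnings.warn(f"{dropped} samples without survival records dropped",
                      stacklevel=2)
    if len(keep) < 4:
        raise ValidationError("need >= 4 matched samples for a median split")
    s = scores[keep]
    t = np.array([surv[sample_ids[i]][0] for i in keep])
    e = np.array([surv[sample_ids[i]][1] for i in keep])
    med = np.median(s)
    low = s <= med
    n_low, n_high = int(low.sum()), int((~low).sum())
    if n_low < 2 or n_high < 2:
        raise ComputationError("a median-split group has fewer than 2 samples")
    if e.sum() == 0:
        raise ComputationError("no events observed; log-rank undefined")
    res = logrank_test(t[low], t[~low], event_observed_A=e[low],
                       event_observed_B=e[~low])
    return SurvivalAssociation(
        module_id=module_id, cancer_id=cancer_id,
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        adjusted_p=float("nan"), group_sizes=(n_low, n_high),
        score_id=score_id,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def survival_screen(module_set, expression_by_cancer, survival_by_cancer,
                    cancer_ids, gene_ids, mirna_ids, level: str = "module",
                    restrict_to_support: bool = True,
                    ) -> list[SurvivalAssociation]:
    """Screen every (module, cancer) pair for survival association.

    Parameters
    ----------
    module_set
        Fitted ModuleSet.
    expression_by_cancer
        Mapping cancer_id -> (X, Y) standardized ExpressionMatrix pair
        (genes, miRNAs) with matching sample ids.
    survival_by_cancer
        Mapping cancer_id -> SurvivalTable; missing tables skip the
        pair with a warning.
    level
        "module" — PC1 of the module's joint gene+miRNA expression;
        "mirna" — each module miRNA's expression is its own score.
    restrict_to_support
        Test only cancers in each module's support K (default); False
        tests every cancer with data.

    All p-values are BH-adjusted as one family; results are ordered by
    (module, cancer[, miRNA]).
    """
    if level not in ("module", "mirna"):
        raise ParameterError(f"unknown level {level!r}")
    results: list[SurvivalAssociation] = []
    for mi, mod in enumerate(module_set.modules, start=1):
        mid = f"M{mi}"
        I, J, K = mod.supports()
        genes = [gene_ids[i] for i in I]
        mirnas = [mirna_ids[j] for j in J]
        cancers = ([cancer_ids[k] for k in K] if restrict_to_support
                   else list(cancer_ids))
        for cid in cancers:
            if cid not in expression_by_cancer:
                warnings.warn(f"no expression for cancer {cid}; pair skipped",
                              stacklevel=2)
                continue
            if cid not in survival_by_cancer:
                warnings.warn(f"no clinical table for cancer {cid}; pair skipped",
                              stacklevel=2)
                continue
            X, Y = expression_by_cancer[cid]
            table = survival_by_cancer[cid]
            if level == "module":
                joint = ExpressionMatrix(
                    np.hstack([X.subset_features(genes).values,
                               Y.subset_features(mirnas).values]),
                    list(X.sample_ids), genes + mirnas,
                    standardized=X.standardized and Y.standardized,
                )
                try:
                    scores = module_pc1(joint)
                    res = median_split_logrank(scores, joint.sample_ids, table,
                                               module_id=mid, cancer_id=cid)
                except (ComputationError, ValidationError) as exc:
                    warnings.warn(f"{mid}/{cid} skipped: {exc}", stacklevel=2)
                    continue
                results.append(res)
            else:
                for m in mirnas:
                    sub = Y.subset_features([m])
                    try:
                        res = median_split_logrank(
                            sub.values[:, 0], sub.sample_ids, table,
                            module_id=mid, cancer_id=cid, score_id=m)
                    except (ComputationError, ValidationError) as exc:
                        warnings.warn(f"{mid}/{cid}/{m} skipped: {exc}",
                                      stacklevel=2)
                        continue
                    results.append(res)
    results.sort(key=lambda r: (r.module_id, r.cancer_id, r.score_id))
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


def significant_pairs(associations, alpha: float = 0.05,
                      ) -> list[tuple[str, str, float]]:
    """Bipartite (module, cancer, adjusted_p) edges passing adjusted p < alpha."""
    return [(r.module_id, r.cancer_id, r.adjusted_p)
            for r in associations if r.adjusted_p < alpha]
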