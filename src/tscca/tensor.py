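"""Expression containers and the cancer-miRNA-gene correlation tensor.

The central object is :class:`CorrelationTensor`, a labelled p × q × M
array whose frontal slice ``k`` holds the sample Pearson correlations
between every gene (rows) and every miRNA (columns) in cancer ``k``.
Slices are computed as ``X_k.T @ Y_k / (n_k - 1)`` on column-standardized
expression matrices, which is exactly the sample Pearson correlation
matrix; dividing by ``n_k - 1`` keeps slices comparable across cancers
with very different cohort sizes and keeps every entry in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "CorrelationTensor",
    "standardize_columns",
    "build_correlation_tensor",
    "align_by_intersection",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A samples × features expression matrix with string labels.

    ``standardized`` records whether every column has been centred to
    mean 0 and scaled to unit sample standard deviation (denominator
    n - 1).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if p != len(self.feature_ids):
            raise ValidationError(
                f"column count {p} != number of feature ids {len(self.feature_ids)}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd - 1) > 1e-6):
                raise ValidationError("standardized flag set but columns are not standardized")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids) -> "ExpressionMatrix":
        """Column subset (in the given order), preserving the flag."""
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in idx]
        if missing:
            raise ValidationError(f"features not present: {missing[:5]}")
        cols = [idx[f] for f in ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.sample_ids), [str(f) for f in ids],
            standardized=self.standardized,
        )


@dataclass
class CorrelationTensor:
    """Labelled 3-way array of gene × miRNA correlations per cancer.

    ``values[i, j, k]`` is the Pearson correlation of gene ``i`` and
    miRNA ``j`` in cancer ``k``.  Residual tensors produced by deflation
    carry ``built_from_data=False`` and are exempt from the [-1, 1]
    entry check.
    """

    values: np.ndarray
    gene_ids: list[str]
    mirna_ids: list[str]
    cancer_ids: list[str]
    sample_counts: list[int] | None = None
    built_from_data: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("tensor values must be a 3-D array")
        p, q, M = self.values.shape
        if M < 1:
            raise ValidationError("tensor needs at least one cancer slice")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        self.cancer_ids = [str(c) for c in self.cancer_ids]
        for ids, n, what in (
            (self.gene_ids, p, "gene"),
            (self.mirna_ids, q, "miRNA"),
            (self.cancer_ids, M, "cancer"),
        ):
            if len(ids) != n:
                raise ValidationError(
                    f"{what} axis has {n} entries but {len(ids)} ids"
                )
            _check_unique(ids, what)
        if self.sample_counts is not None and len(self.sample_counts) != M:
            raise ValidationError("sample_counts length must equal number of cancers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tensor contains non-finite entries")
        if self.built_from_data and np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValidationError(
                "correlation entries outside [-1, 1]; use built_from_data=False "
                "for residual or synthetic tensors"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slice(self, k: int) -> np.ndarray:
        """Frontal slice A_k (genes × miRNAs) for cancer index ``k``."""
        return self.values[:, :, k]

    def with_values(self, values: np.ndarray, built_from_data: bool = False
                    ) -> "CorrelationTensor":
        return replace(self, values=values, built_from_data=built_from_data)


def standardize_columns(E: ExpressionMatrix) -> ExpressionMatrix:
    """Centre each column to mean 0 and scale to unit sd (ddof=1).

    Requires at least 3 samples; a constant column is an error naming
    the feature (zero variance cannot be standardized).
    """
    if E.n_samples < 3:
        raise ValidationError(
            f"standardization requires >= 3 samples, got {E.n_samples}"
        )
    mu = E.values.mean(axis=0)
    sd = E.values.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValidationError(
            f"constant column cannot be standardized: feature {E.feature_ids[zero[0]]!r}"
        )
    return ExpressionMatrix(
        (E.values - mu) / sd, list(E.sample_ids), list(E.feature_ids),
        standardized=True,
    )


def build_correlation_tensor(
    pairs: list[tuple[str, ExpressionMatrix, ExpressionMatrix]],
    *,
    scale: bool = True,
) -> CorrelationTensor:
    """Assemble the correlation tensor from per-cancer (X_k, Y_k) pairs.

    Parameters
    ----------
    pairs
        List of ``(cancer_id, X, Y)`` with X the gene matrix and Y the
        miRNA matrix; X and Y must share sample counts within a pair,
        and gene/miRNA axes must match exactly across cancers.
        Unstandardized inputs are standardized internally.
    scale
        If True (default), slice k is ``X.T @ Y / (n_k - 1)`` — the
        exact sample Pearson correlation matrix.  If False, the plain
        cross-product ``X.T @ Y`` convention is used instead and the
        result is flagged ``built_from_data=False``.
    """
    if not pairs:
        raise ValidationError("no cancer pairs given")
    cancer_ids = [str(c) for c, _, _ in pairs]
    _check_unique(cancer_ids, "cancer")
    gene_ids = list(pairs[0][1].feature_ids)
    mirna_ids = list(pairs[0][2].feature_ids)
    slices = []
    counts = []
    for cid, X, Y in pairs:
        if X.feature_ids != gene_ids:
            missing = sorted(set(gene_ids) ^ set(X.feature_ids))
            raise ValidationError(
                f"gene axis mismatch in cancer {cid!r}; differing ids: {missing[:5]}"
            )
        if Y.feature_ids != mirna_ids:
            missing = sorted(set(mirna_ids) ^ set(Y.feature_ids))
            raise ValidationError(
                f"miRNA axis mismatch in cancer {cid!r}; differing ids: {missing[:5]}"
            )
        if X.n_samples != Y.n_samples:
            raise ValidationError(
                f"cancer {cid!r}: gene matrix has {X.n_samples} samples but "
                f"miRNA matrix has {Y.n_samples}"
            )
        if X.n_samples < 3:
            raise ValidationError(f"cancer {cid!r}: need >= 3 samples")
        if not X.standardized:
            X = standardize_columns(X)
        if not Y.standardized:
            Y = standardize_columns(Y)
        n = X.n_samples
        S = X.values.T @ Y.values
        if scale:
            S = S / (n - 1)
            # exact correlations can exceed 1 by float rounding only
            np.clip(S, -1.0, 1.0, out=S)
        slices.append(S)
        counts.append(n)
    values = np.stack(slices, axis=2)
    return CorrelationTensor(
        values, gene_ids, mirna_ids, cancer_ids,
        sample_counts=counts, built_from_data=scale,
    )


def align_by_intersection(
    pairs: list[tuple[str, ExpressionMatrix, ExpressionMatrix]],
) -> list[tuple[str, ExpressionMatrix, ExpressionMatrix]]:
    """Restrict every cancer's matrices to the shared gene/miRNA ids.

    Convenience for inputs whose feature axes differ across cancers;
    ids are kept in the order of the first cancer.  Strict matching in
    :func:`build_correlation_tensor` remains the default path.
    """
    if not pairs:
        raise ValidationError("no cancer pairs given")
    genes = set(pairs[0][1].feature_ids)
    mirnas = set(pairs[0][2].feature_ids)
    for _, X, Y in pairs[1:]:
        genes &= set(X.feature_ids)
        mirnas &= set(Y.feature_ids)
    if not genes or not mirnas:
        raise ValidationError("empty gene or miRNA intersection across cancers")
    gene_order = [g for g in pairs[0][1].feature_ids if g in genes]
    mirna_order = [m for m in pairs[0][2].feature_ids if m in mirnas]
    return [
        (c, X.subset_features(gene_order), Y.subset_features(mirna_order))
        for c, X, Y in pairs
    ]
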