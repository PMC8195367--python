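"""ℓ0-constrained tensor sparse CCA: projection, solver, deflation.

The model seeks unit vectors u (genes), v (miRNAs), w (cancers) with at
most k_u / k_v / k_w nonzeros maximizing the trilinear form

    Σ_k w_k · (uᵀ A_k v),

where A_k is the gene × miRNA correlation matrix of cancer k.  Each
block update has a closed form: with the other two factors fixed, the
optimal factor is the k-sparse projection of a score vector, normalized
(keep the k largest-magnitude entries, zero the rest, divide by the
ℓ2 norm).  Block-coordinate ascent over (u, v, w) therefore increases
the objective monotonically and converges to a fixed point; the value
d of the trilinear form there is the module's singular value.  Further
modules come from deflation: subtract d·(u∘v∘w) and refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError, ValidationError
from .tensor import CorrelationTensor

__all__ = [
    "SparsityParams",
    "SolverOptions",
    "Module",
    "ModuleSet",
    "ksparse_project",
    "solve_subproblem",
    "objective",
    "tscca_rank1",
    "tscca_multi",
    "scca_rank1",
]


@dataclass(frozen=True)
class SparsityParams:
    """ℓ0 budgets: maximum nonzero genes (k_u), miRNAs (k_v), cancers (k_w)."""

    k_u: int
    k_v: int
    k_w: int

    def validate(self, shape: tuple[int, int, int]) -> None:
        p, q, M = shape
        for k, n, name in ((self.k_u, p, "k_u"), (self.k_v, q, "k_v"),
                           (self.k_w, M, "k_w")):
            if not 1 <= k <= n:
                raise ParameterError(f"{name}={k} outside [1, {n}]")


@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the block-coordinate solver.

    tol
        Convergence threshold on the max-norm change of u, v and w
        between sweeps.
    max_iter
        Sweep cap; non-convergence is reported, not raised.
    init
        "svd" — Algorithm start: w uniform with unit norm, (u, v) the
        leading singular pair of Σ w_k A_k.  "slices" — additionally
        try w = e_k for every cancer k and keep the best objective
        (useful when signal cancels in the uniform-w average, as with
        sign-opposite co-expression across cancers).
    restarts
        Number of extra seeded random initializations (best kept).
    seed
        Seed for the random restarts; required when restarts > 0.
    track_objective
        Record the objective after every block update in Module.trace.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    init: str = "slices"
    restarts: int = 0
    seed: int | None = None
    track_objective: bool = False


@dataclass
class Module:
    """One sparse rank-1 factor triple and its bookkeeping.

    u, v, w are unit vectors with supports I, J, K (indices of nonzero
    gene/miRNA/cancer weights); d ≥ 0 is the singular value (trilinear
    form at the fixed point).  Gauge: (u, v) are jointly signed so the
    largest-magnitude entry of v is positive; w keeps its sign pattern
    (opposite-sign cancer weights are biologically meaningful).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    d: float
    iterations: int = 0
    converged: bool = True
    trace: list[float] = field(default_factory=list)

    @property
    def I(self) -> np.ndarray:  # noqa: E743 — field named for the gene support
        return np.nonzero(self.u)[0]

    @property
    def J(self) -> np.ndarray:
        return np.nonzero(self.v)[0]

    @property
    def K(self) -> np.ndarray:
        return np.nonzero(self.w)[0]

    def supports(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.I, self.J, self.K

    def cells(self) -> set[tuple[int, int, int]]:
        """The module as a set of (gene, miRNA, cancer) index triples."""
        return {(i, j, k) for i in self.I for j in self.J for k in self.K}


@dataclass
class ModuleSet:
    """Ordered modules from deflation plus the cancer-weight matrix W."""

    modules: list[Module]
    W: np.ndarray
    residual: CorrelationTensor
    params: SparsityParams

    @property
    def r(self) -> int:
        return len(self.modules)

    @property
    def singular_values(self) -> np.ndarray:
        return np.array([m.d for m in self.modules])


def ksparse_project(z: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest-|z| entries, zero the rest.

    Ties at the k-th magnitude are broken toward the lowest index, so
    the operator is deterministic and runs are bit-reproducible.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ParameterError("score vector must be 1-D")
    if not 1 <= k <= z.size:
        raise ParameterError(f"k={k} outside [1, {z.size}]")
    if k == z.size:
        return z.copy()
    # stable sort on -|z| puts equal magnitudes in index order
    order = np.argsort(-np.abs(z), kind="stable")
    out = np.zeros_like(z)
    keep = order[:k]
    out[keep] = z[keep]
    return out


def solve_subproblem(z: np.ndarray, k: int) -> np.ndarray:
    """argmax of uᵀz over unit u with at most k nonzeros: Π(z,k)/‖Π(z,k)‖."""
    pz = ksparse_project(z, k)
    nrm = np.linalg.norm(pz)
    if nrm == 0.0:
        raise DegenerateInputError(
            "score vector is identically zero; perturb the tensor or lower k"
        )
    return pz / nrm


def objective(A: CorrelationTensor | np.ndarray, u: np.ndarray, v: np.ndarray,
              w: np.ndarray) -> float:
    """Trilinear form Σ_k w_k (uᵀ A_k v) — the tensor contracted with u, v, w."""
    T = A.values if isinstance(A, CorrelationTensor) else np.asarray(A, dtype=float)
    if T.shape != (len(u), len(v), len(w)):
        raise ValidationError(
            f"dimension mismatch: tensor {T.shape} vs factors "
            f"({len(u)}, {len(v)}, {len(w)})"
        )
    return float(np.einsum("ijk,i,j,k->", T, u, v, w))


def _leading_pair(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading left/right singular vectors of a dense matrix."""
    U, _, Vt = np.linalg.svd(C, full_matrices=False)
    return U[:, 0], Vt[0, :]


def _fix_gauge(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # joint sign flip leaves every uᵀA_k v (hence w and d) unchanged
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        return -u, -v
    return u, v


def _bcd(T: np.ndarray, params: SparsityParams, opts: SolverOptions,
         u0: np.ndarray, v0: np.ndarray, w0: np.ndarray) -> Module:
    """One block-coordinate ascent run from the given starting triple."""
    p, q, M = T.shape
    u, v, w = u0, v0, w0
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        C = np.tensordot(T, w, axes=([2], [0]))  # Σ w_k A_k
        u_new = solve_subproblem(C @ v, params.k_u)
        # the starting (v, w) may be dense (SVD init), so the first
        # sweep's intermediate objectives compare against an infeasible
        # point; the trace records the feasible ascent only
        if opts.track_objective and it > 1:
            trace.append(objective(T, u_new, v, w))
        v_new = solve_subproblem(C.T @ u_new, params.k_v)
        if opts.track_objective and it > 1:
            trace.append(objective(T, u_new, v_new, w))
        z_w = np.einsum("ijk,i,j->k", T, u_new, v_new)
        w_new = solve_subproblem(z_w, params.k_w)
        if opts.track_objective:
            trace.append(objective(T, u_new, v_new, w_new))
        delta = max(
            np.max(np.abs(u_new - u)),
            np.max(np.abs(v_new - v)),
            np.max(np.abs(w_new - w)),
        )
        u, v, w = u_new, v_new, w_new
        if delta < opts.tol:
            converged = True
            break
    d = objective(T, u, v, w)
    u, v = _fix_gauge(u, v)
    return Module(u=u, v=v, w=w, d=d, iterations=it, converged=converged,
                  trace=trace)


def _initial_triples(T: np.ndarray, params: SparsityParams, opts: SolverOptions):
    """Yield starting (u, v, w) triples per the configured init strategy."""
    p, q, M = T.shape
    starts = []
    w_flat = np.full(M, 1.0 / np.sqrt(M))
    starts.append(w_flat)
    if opts.init == "slices":
        for k in range(M):
            e = np.zeros(M)
            e[k] = 1.0
            starts.append(e)
    elif opts.init != "svd":
        raise ParameterError(f"unknown init strategy {opts.init!r}")
    for w0 in starts:
        C = np.tensordot(T, w0, axes=([2], [0]))
        if not np.any(C):
            continue
        u0, v0 = _leading_pair(C)
        yield u0, v0, w0
    if opts.restarts:
        if opts.seed is None:
            raise ParameterError("restarts > 0 requires a seed")
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.restarts):
            u0 = solve_subproblem(rng.standard_normal(p), params.k_u)
            v0 = solve_subproblem(rng.standard_normal(q), params.k_v)
            w0 = solve_subproblem(rng.standard_normal(M), params.k_w)
            yield u0, v0, w0


def tscca_rank1(A: CorrelationTensor | np.ndarray, params: SparsityParams,
                options: SolverOptions | None = None) -> Module:
    """Fit one sparse rank-1 module by block-coordinate ascent.

    Alternates the three closed-form updates until the factors change
    by less than ``tol`` in max-norm.  Multiple initializations (see
    :class:`SolverOptions`) are run to completion and the triple with
    the best objective is returned; d ≥ 0 holds at every fixed point
    because the w-update aligns w with its score vector.
    """
    opts = options or SolverOptions()
    T = A.values if isinstance(A, CorrelationTensor) else np.asarray(A, dtype=float)
    if T.ndim != 3:
        raise ValidationError("expected a 3-way tensor")
    if not np.all(np.isfinite(T)):
        raise ValidationError("tensor contains non-finite entries")
    params.validate(T.shape)

    best: Module | None = None
    degenerate: DegenerateInputError | None = None
    for u0, v0, w0 in _initial_triples(T, params, opts):
        try:
            mod = _bcd(T, params, opts, u0, v0, w0)
        except DegenerateInputError as exc:
            degenerate = exc
            continue
        if best is None or mod.d > best.d:
            best = mod
    if best is None:
        raise degenerate or DegenerateInputError(
            "tensor is identically zero; no module can be fitted"
        )
    return best


def tscca_multi(A: CorrelationTensor, r: int, params: SparsityParams,
                options: SolverOptions | None = None) -> ModuleSet:
    """Extract r modules by successive rank-1 fits and deflation.

    After each fit the rank-1 term d·(u∘v∘w) is subtracted from the
    working tensor, so A = Σ_j d_j·(u_j∘v_j∘w_j) + residual holds
    exactly.  Column j of W is module j's cancer-weight vector w_j.
    If the residual degenerates to zero before r modules are found the
    modules found so far are returned with a warning.
    """
    if r < 1:
        raise ParameterError(f"r={r} must be >= 1")
    if not isinstance(A, CorrelationTensor):
        raise ValidationError("tscca_multi expects a CorrelationTensor")
    T = A.values.copy()
    modules: list[Module] = []
    for _ in range(r):
        try:
            mod = tscca_rank1(T, params, options)
        except DegenerateInputError:
            warnings.warn(
                f"residual tensor degenerate after {len(modules)} modules; "
                f"stopping early", stacklevel=2)
            break
        modules.append(mod)
        T -= mod.d * np.einsum("i,j,k->ijk", mod.u, mod.v, mod.w)
    M = A.shape[2]
    W = (np.stack([m.w for m in modules], axis=1)
         if modules else np.zeros((M, 0)))
    residual = A.with_values(T, built_from_data=False)
    return ModuleSet(modules=modules, W=W, residual=residual, params=params)


def scca_rank1(Z: np.ndarray, k_u: int, k_v: int,
               options: SolverOptions | None = None) -> Module:
    """Single-matrix ℓ0 sparse CCA: the M = 1, k_w = 1 special case.

    The baseline for one cancer: fit the one-slice tensor with the full
    cancer budget, returning a module whose cancer support is {0}.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValidationError("expected a 2-D correlation matrix")
    T = Z[:, :, None]
    return tscca_rank1(T, SparsityParams(k_u, k_v, 1), options)
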