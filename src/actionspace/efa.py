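"""Exploratory factor analysis: principal-axis factoring with direct-oblimin
rotation, factor-number diagnostics, loading interpretation and factor scores.

Extraction is classic iterated principal axis factoring: squared multiple
correlations seed the communalities, the reduced correlation matrix is
eigendecomposed, and communalities are updated until they stabilise.  The
oblique rotation minimises the direct-oblimin criterion (gamma = 0, i.e.
direct quartimin) by Jennrich's gradient-projection algorithm over oblique
rotation matrices; the best of several random starts plus the identity start
is kept.  Factor-number selection offers the eigenvalue scree and Horn's
parallel analysis against random-data reference eigenvalues.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DegenerateDataError, ValidationError
from .ratings import MeanRatingMatrix

__all__ = [
    "ScreeResult", "EfaModel", "LoadingInterpretation",
    "scree", "parallel_analysis", "paf_extract", "oblimin_rotate",
    "interpret", "variance_explained", "factor_scores", "centrality_test",
    "fit_efa",
]


# ---------------------------------------------------------------------------
# factor-number diagnostics

@dataclass
class ScreeResult:
    eigenvalues: np.ndarray        # descending, unreduced correlation matrix
    pa_reference: np.ndarray | None = None
    n_factors_pa: int | None = None
    n_factors_scree: int | None = None


def scree(R: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the (unreduced) correlation matrix."""
    r = np.asarray(R, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    ev = np.linalg.eigvalsh(r)
    return ev[::-1]


def reduced_eigenvalues(R: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the common-factor (reduced) correlation
    matrix: squared multiple correlations replace the unit diagonal."""
    r = np.asarray(R, dtype=float)
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    reduced = r.copy()
    np.fill_diagonal(reduced, smc)
    return np.linalg.eigvalsh(reduced)[::-1]


def parallel_analysis(observed: np.ndarray, n: int, p: int, reps: int = 1000,
                      criterion: str = "q95", seed: int | None = 0,
                      percentile: float = 95.0, method: str = "fa") -> ScreeResult:
    """Horn's parallel analysis for factor retention.

    Simulates ``reps`` standard-normal n x p data sets, collects the
    descending eigenvalues of their correlation matrices, aggregates per rank
    by the chosen criterion (``q95``, the Glorfeld-corrected 95th percentile
    and the default; or ``mean``, Horn's original), and retains factors while
    the observed eigenvalue exceeds the reference.

    ``method`` selects the eigenvalue flavour compared on both sides:
    ``"fa"`` (default) uses common-factor eigenvalues of the reduced matrix
    (squared multiple correlations on the diagonal), the comparison under
    which weak-but-real minor factors beat the random reference; ``"pc"``
    uses the unreduced correlation-matrix eigenvalues.  For ``"fa"``,
    ``observed`` must be the correlation matrix itself (2-D); for ``"pc"``
    either the matrix or a pre-computed descending eigenvalue vector.
    """
    if reps < 100:
        raise ValidationError("parallel analysis needs reps >= 100")
    observed = np.asarray(observed, dtype=float)
    if method == "fa":
        if observed.ndim != 2:
            raise ValidationError("method='fa' needs the correlation matrix")
        obs = reduced_eigenvalues(observed)
        extract = reduced_eigenvalues
    elif method == "pc":
        obs = scree(observed) if observed.ndim == 2 else observed
        extract = lambda r: scree(r)  # noqa: E731
    else:
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    sims = np.empty((reps, p))
    for i in range(reps):
        x = rng.standard_normal((n, p))
        sims[i] = extract(np.corrcoef(x, rowvar=False))
    if criterion == "mean":
        ref = sims.mean(axis=0)
    elif criterion == "q95":
        ref = np.percentile(sims, percentile, axis=0)
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    keep = 0
    for o, r in zip(obs, ref):
        if o > r:
            keep += 1
        else:
            break
    return ScreeResult(eigenvalues=obs, pa_reference=ref, n_factors_pa=keep)


# ---------------------------------------------------------------------------
# extraction

def paf_extract(R: pd.DataFrame | np.ndarray, k: int, tol: float = 1e-3,
                max_iter: int = 100):
    """Iterated principal-axis factoring.

    Returns ``(loadings, communalities, converged, n_iter)``.  Initial
    communalities are squared multiple correlations; each iteration
    eigendecomposes the reduced matrix, rebuilds loadings from the top ``k``
    components (negative eigenvalues truncated at zero) and stops when the
    largest communality change falls below ``tol``.  Heywood communalities
    are capped at 1.
    """
    r = np.asarray(R, dtype=float)
    p = r.shape[0]
    if k < 1 or k >= p:
        raise ValidationError(f"need 1 <= k < p, got k={k}, p={p}")
    try:
        r_inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("correlation matrix is singular") from exc
    h2 = 1.0 - 1.0 / np.diag(r_inv)            # squared multiple correlations
    converged = False
    n_iter = 0
    loadings = np.zeros((p, k))
    for n_iter in range(1, max_iter + 1):
        reduced = r.copy()
        np.fill_diagonal(reduced, h2)
        ev, vec = np.linalg.eigh(reduced)
        idx = np.argsort(ev)[::-1][:k]
        lam = np.clip(ev[idx], 0.0, None)
        loadings = vec[:, idx] * np.sqrt(lam)
        h2_new = np.clip((loadings ** 2).sum(axis=1), None, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    # canonical sign: each column's largest-|loading| positive
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
    return loadings, h2, converged, n_iter


# ---------------------------------------------------------------------------
# direct oblimin rotation by gradient projection

def _oblimin_criterion(L: np.ndarray, gamma: float):
    """Direct-oblimin criterion value and gradient w.r.t. the rotated
    loadings (gamma = 0 gives direct quartimin)."""
    p, k = L.shape
    L2 = L ** 2
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    if gamma != 0:
        X = (np.eye(p) - np.full((p, p), gamma / p)) @ X
    f = np.sum(L2 * X) / 4.0
    G = L * X
    return f, G


def _gpf_oblique(A: np.ndarray, T0: np.ndarray, gamma: float,
                 tol: float = 1e-6, max_iter: int = 500):
    """Gradient projection on the oblique rotation manifold (columns of T of
    unit length).  Returns (pattern, phi, criterion, converged)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)      # project onto tangent space
        s = np.sqrt((Gp ** 2).sum())
        if s < tol:
            converged = True
            break
        al = 2.0 * al
        for _inner in range(20):
            X = T - al * Gp
            X /= np.sqrt((X ** 2).sum(axis=0))
            try:
                Xi = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Xi.T
            ft, Gq = _oblimin_criterion(Lt, gamma)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        else:
            break
        T, Ti, L, f = X, Xi, Lt, ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, f, converged


def oblimin_rotate(unrotated: np.ndarray, gamma: float = 0.0, restarts: int = 10,
                   seed: int | None = 0, tol: float = 1e-6, max_iter: int = 500):
    """Direct-oblimin rotation of an unrotated loading matrix.

    Runs gradient projection from the identity start plus ``restarts`` random
    oblique starts and keeps the lowest criterion value.  Factors are
    reflected so each structure column's largest-|loading| is positive and
    ordered by descending sum of squared structure loadings.

    Returns ``(pattern, structure, phi)``.
    """
    A = np.asarray(unrotated, dtype=float)
    p, k = A.shape
    if k == 1:
        return A.copy(), A.copy(), np.ones((1, 1))
    rng = np.random.default_rng(seed)
    starts = [np.eye(k)]
    for _ in range(restarts):
        M = rng.standard_normal((k, k))
        q, _r = np.linalg.qr(M)
        starts.append(q)
    best = None
    for T0 in starts:
        L, phi, f, conv = _gpf_oblique(A, T0, gamma, tol=tol, max_iter=max_iter)
        if conv and (best is None or f < best[2]):
            best = (L, phi, f)
    if best is None:
        raise ConvergenceError(
            f"oblimin rotation failed to converge from {len(starts)} starts "
            f"(p={p}, k={k}, gamma={gamma})")
    pattern, phi, _f = best
    structure = pattern @ phi
    # reflect: largest-|structure-loading| per column positive
    for j in range(k):
        if structure[np.argmax(np.abs(structure[:, j])), j] < 0:
            pattern[:, j] *= -1
            structure[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    # order by descending sum of squared structure loadings
    order = np.argsort(-(structure ** 2).sum(axis=0), kind="stable")
    pattern = pattern[:, order]
    structure = structure[:, order]
    phi = phi[np.ix_(order, order)]
    np.fill_diagonal(phi, 1.0)
    return pattern, structure, phi


# ---------------------------------------------------------------------------
# assembled model

@dataclass
class EfaModel:
    """Extraction + rotation result for ``k`` common factors."""

    k: int
    items: list[str]
    unrotated: np.ndarray
    pattern: np.ndarray
    structure: np.ndarray
    phi: np.ndarray
    communalities: np.ndarray
    var_explained_pct: np.ndarray
    total_var_pct: float
    converged: bool
    n_iter: int
    corr: pd.DataFrame | None = None

    @property
    def uniquenesses(self) -> np.ndarray:
        return 1.0 - self.communalities

    def pattern_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.pattern, index=self.items, columns=cols)

    def structure_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.structure, index=self.items, columns=cols)

    def phi_frame(self) -> pd.DataFrame:
        cols = [f"factor_{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.phi, index=cols, columns=cols)


def variance_explained(pattern: np.ndarray, structure: np.ndarray,
                       phi: np.ndarray, p: int):
    """Variance accounting of an oblique solution.

    The total percentage is convention-free: 100 * sum(h^2) / p with
    h^2 = diag(pattern @ phi @ pattern.T).  Per-factor splits use the
    diagonal of Lambda' Lambda Phi (pattern-based, Phi-weighted), which sums
    to the same total.
    """
    pattern = np.asarray(pattern, dtype=float)
    phi = np.asarray(phi, dtype=float)
    per_factor = 100.0 * np.diag(pattern.T @ pattern @ phi) / p
    h2 = np.einsum("ij,jk,ik->i", pattern, phi, pattern)
    total = 100.0 * h2.sum() / p
    return per_factor, float(total)


def fit_efa(source: MeanRatingMatrix | pd.DataFrame | np.ndarray, k: int,
            gamma: float = 0.0, restarts: int = 10, seed: int | None = 0,
            tol: float = 1e-3, max_iter: int = 100,
            items: list[str] | None = None) -> EfaModel:
    """PAF extraction + direct-oblimin rotation on a mean-rating matrix or a
    pre-computed correlation matrix."""
    from .adequacy import pearson_corr

    if isinstance(source, MeanRatingMatrix):
        R = pearson_corr(source)
    elif isinstance(source, pd.DataFrame):
        arr = source.to_numpy(dtype=float)
        is_corr = (arr.shape[0] == arr.shape[1]
                   and np.allclose(np.diag(arr), 1.0, atol=1e-8)
                   and np.allclose(arr, arr.T, atol=1e-8))
        R = source if is_corr else pearson_corr(source)
    else:
        R = pd.DataFrame(np.asarray(source, dtype=float))
        if items is not None:
            R.index = R.columns = items
    item_labels = list(R.columns)
    r = R.to_numpy(dtype=float)
    unrotated, h2, converged, n_iter = paf_extract(r, k, tol=tol, max_iter=max_iter)
    pattern, structure, phi = oblimin_rotate(
        unrotated, gamma=gamma, restarts=restarts, seed=seed)
    per_factor, total = variance_explained(pattern, structure, phi, p=r.shape[0])
    return EfaModel(
        k=k, items=item_labels, unrotated=unrotated, pattern=pattern,
        structure=structure, phi=phi, communalities=h2,
        var_explained_pct=per_factor, total_var_pct=total,
        converged=converged, n_iter=n_iter, corr=R,
    )


# ---------------------------------------------------------------------------
# interpretation

@dataclass
class ItemAssignment:
    item: str
    primary_factor: int | None      # 0-based factor index, None if unassigned
    primary_loading: float
    is_substantial: bool


@dataclass
class LoadingInterpretation:
    assignments: list[ItemAssignment]
    primary_cut: float
    cross_cut: float
    per_factor: dict[int, list[str]] = field(default_factory=dict)

    def substantial_items(self, factor: int) -> list[str]:
        return self.per_factor.get(factor, [])

    def loading_sign(self, item: str) -> float:
        for a in self.assignments:
            if a.item == item:
                return float(np.sign(a.primary_loading))
        raise KeyError(item)


def interpret(structure: np.ndarray | pd.DataFrame, items: list[str] | None = None,
              primary_cut: float = 0.5, cross_cut: float = 0.3) -> LoadingInterpretation:
    """Substantial-loading rule: an item is substantial on its largest-|loading|
    factor iff that loading's magnitude is >= ``primary_cut`` and every other
    |loading| is < ``cross_cut``."""
    if isinstance(structure, pd.DataFrame):
        items = list(structure.index)
        s = structure.to_numpy(dtype=float)
    else:
        s = np.asarray(structure, dtype=float)
        items = items or [f"item_{i}" for i in range(s.shape[0])]
    assignments = []
    per_factor: dict[int, list[str]] = {}
    for i, item in enumerate(items):
        row = s[i]
        j = int(np.argmax(np.abs(row)))
        primary = row[j]
        others = np.abs(np.delete(row, j))
        substantial = bool(np.abs(primary) >= primary_cut and
                           (others < cross_cut).all())
        assignments.append(ItemAssignment(
            item=item, primary_factor=j if substantial else None,
            primary_loading=float(primary), is_substantial=substantial))
        if substantial:
            per_factor.setdefault(j, []).append(item)
    return LoadingInterpretation(
        assignments=assignments, primary_cut=primary_cut, cross_cut=cross_cut,
        per_factor=per_factor)


# ---------------------------------------------------------------------------
# factor scores and the centrality contrast

def factor_scores(matrix: MeanRatingMatrix | pd.DataFrame, model: EfaModel,
                  method: str = "regression") -> pd.DataFrame:
    """Thurstone regression factor scores: Z @ R^-1 @ structure on
    column-standardised data."""
    if method != "regression":
        raise ValidationError(f"unknown factor-score method {method!r}")
    df = matrix.values if isinstance(matrix, MeanRatingMatrix) else matrix
    if list(df.columns) != model.items:
        if set(df.columns) >= set(model.items):
            df = df[model.items]
        else:
            raise ValidationError("matrix columns do not match model items")
    z = (df - df.mean()) / df.std(ddof=1)
    r = model.corr.to_numpy(dtype=float) if model.corr is not None else \
        np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    w = np.linalg.solve(r, model.structure)
    scores = z.to_numpy(dtype=float) @ w
    return pd.DataFrame(scores, index=df.index,
                        columns=[f"factor_{j + 1}" for j in range(model.k)])


def centrality_test(scores: pd.DataFrame, groups) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test on each action's Euclidean distance
    to the origin of the factor-score space, between two groups of actions."""
    g = np.asarray(groups)
    if g.shape[0] != scores.shape[0]:
        raise ValidationError("groups must label every action")
    dist = np.sqrt((scores.to_numpy(dtype=float) ** 2).sum(axis=1))
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError("exactly two groups required")
    a, b = dist[g == labels[0]], dist[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 actions")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(dist) - 2, float(p)
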