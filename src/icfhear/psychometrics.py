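"""Validation statistics: descriptives, floor/ceiling effects, Cronbach's
alpha, Mann-Whitney U, KMO, Bartlett's sphericity, and principal-axis
factoring with Promax rotation.

Conventions follow the common social-science defaults: Pearson
correlations on 0-4 grades with pairwise-complete deletion, listwise
deletion for alpha, Kaiser retention on the unreduced correlation matrix,
Promax power 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .item_bank import ItemBank
from .responses import Cohort
from .scoring import coded_value

log = logging.getLogger(__name__)

__all__ = [
    "ItemDescriptives",
    "ReliabilityResult",
    "GroupTestResult",
    "EFAResult",
    "response_matrix",
    "describe_items",
    "cronbach_alpha",
    "cronbach_alpha_matrix",
    "mann_whitney",
    "kmo",
    "bartlett_sphericity",
    "varimax",
    "promax",
    "paf_promax",
    "FLOOR_CEILING_CUTOFF",
]

#: an item shows a floor/ceiling effect when more than this fraction of
#: respondents chose the scale minimum/maximum
FLOOR_CEILING_CUTOFF = 0.15

# ---------------------------------------------------------------------------
# data extraction


def response_matrix(
    cohort: Cohort,
    bank: ItemBank,
    item_ids: list[str] | None = None,
    coded: bool = True,
) -> pd.DataFrame:
    """Respondent-by-item numeric matrix; non-gradable responses become NaN.

    With ``coded=True`` facilitator items are mirrored so higher always
    means more hardship; with ``coded=False`` raw grades are returned.
    """
    item_ids = list(item_ids) if item_ids is not None else bank.item_ids
    rows = []
    for r in cohort:
        row = []
        for item_id in item_ids:
            v = r.responses[item_id]
            if not v.gradable:
                row.append(np.nan)
            elif coded:
                row.append(float(coded_value(bank[item_id], v)))
            else:
                row.append(float(v.grade))
        rows.append(row)
    return pd.DataFrame(rows, index=[r.id for r in cohort], columns=item_ids, dtype=float)


# ---------------------------------------------------------------------------
# descriptives


@dataclass(frozen=True)
class ItemDescriptives:
    item_id: str
    n_graded: int
    n_total: int
    min: float
    max: float
    mean: float
    sd: float
    median: float
    floor_proportion: float
    ceiling_proportion: float
    floor_present: bool
    ceiling_present: bool
    defined: bool = True


def describe_items(cohort: Cohort, bank: ItemBank,
                   item_ids: list[str] | None = None) -> dict[str, ItemDescriptives]:
    """Per-item descriptive statistics over graded responses (raw 0-4 scale).

    Floor/ceiling proportions use all respondents as denominator; the
    effect is flagged when the proportion strictly exceeds 15%.
    """
    mat = response_matrix(cohort, bank, item_ids, coded=False)
    out: dict[str, ItemDescriptives] = {}
    n_total = len(mat)
    for item_id in mat.columns:
        col = mat[item_id]
        graded = col.dropna()
        n = len(graded)
        floor_p = float((col == 0).sum()) / n_total
        ceil_p = float((col == 4).sum()) / n_total
        if n == 0:
            out[item_id] = ItemDescriptives(
                item_id, 0, n_total, math.nan, math.nan, math.nan, math.nan,
                math.nan, floor_p, ceil_p,
                floor_p > FLOOR_CEILING_CUTOFF, ceil_p > FLOOR_CEILING_CUTOFF,
                defined=False,
            )
            continue
        out[item_id] = ItemDescriptives(
            item_id=item_id,
            n_graded=n,
            n_total=n_total,
            min=float(graded.min()),
            max=float(graded.max()),
            mean=float(graded.mean()),
            sd=float(graded.std(ddof=1)) if n > 1 else 0.0,
            median=float(graded.median()),
            floor_proportion=floor_p,
            ceiling_proportion=ceil_p,
            floor_present=floor_p > FLOOR_CEILING_CUTOFF,
            ceiling_present=ceil_p > FLOOR_CEILING_CUTOFF,
        )
    return out


# ---------------------------------------------------------------------------
# reliability


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    n_items: int
    n_complete_respondents: int
    item_total_correlations: dict[str, float] = field(default_factory=dict)


def cronbach_alpha_matrix(X: np.ndarray) -> float:
    """Alpha for a complete respondent-by-item matrix:
    (k/(k-1)) * (1 - sum of item variances / variance of the total)."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 2:
        raise ValueError("alpha needs at least 2 respondents")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)


def cronbach_alpha(cohort: Cohort, item_ids: list[str], bank: ItemBank) -> ReliabilityResult:
    """Cronbach's alpha over an item subset with listwise deletion.

    Facilitator items enter hardship-coded (mirrored) so all items point
    the same way.
    """
    if len(item_ids) < 2:
        raise ValueError("alpha needs at least 2 items")
    mat = response_matrix(cohort, bank, item_ids, coded=True)
    complete = mat.dropna(axis=0, how="any")
    n = len(complete)
    if n < 2:
        raise ValueError(
            f"only {n} complete respondents after listwise deletion over {len(item_ids)} items"
        )
    X = complete.to_numpy()
    alpha = cronbach_alpha_matrix(X)
    totals = X.sum(axis=1)
    itc: dict[str, float] = {}
    for j, item_id in enumerate(item_ids):
        rest = totals - X[:, j]
        if X[:, j].std() == 0 or rest.std() == 0:
            itc[item_id] = math.nan
        else:
            itc[item_id] = float(np.corrcoef(X[:, j], rest)[0, 1])
    return ReliabilityResult(
        alpha=float(alpha),
        n_items=len(item_ids),
        n_complete_respondents=n,
        item_total_correlations=itc,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float  # min(U_A, U_B)
    u1: float
    z_value: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"


EXACT_LIMIT = 400  # exact permutation null when n1 * n2 <= this


def _exact_u_pvalue(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided p from the exact permutation distribution of U.

    Dynamic programme over doubled midranks (integers), counting the
    subsets of size ``n1`` attaining each doubled rank sum.  The
    distribution is symmetric about n1*n2/2, so the two-sided p sums
    probability at least as far from the centre as observed.
    """
    n = len(ranks)
    n2 = n - n1
    r2 = np.rint(2 * ranks).astype(np.int64)
    max_sum = int(np.sort(r2)[-n1:].sum()) if n1 else 0
    # ways[k, s] = number of k-subsets with doubled rank sum s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for r in r2:
        # 0/1 knapsack update, descending k
        for k in range(n1, 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    counts = ways[n1]
    total = counts.sum()
    # doubled U values: 2U = 2R - n1(n1+1)
    offset = n1 * (n1 + 1)
    center = n1 * n2  # doubled-scale centre of 2U
    dev_obs = abs(2 * u_obs - center) - 1e-9
    sums = np.arange(max_sum + 1)
    dev = np.abs((sums - offset) - center)
    p = counts[dev >= dev_obs].sum() / total
    return float(min(1.0, p))


def mann_whitney(group_a, group_b) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Uses the exact permutation distribution when n1*n2 <= 400, otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # all pooled values identical
        return GroupTestResult(u_min, u1, 0.0, 1.0, n1, n2, "degenerate")
    sigma = math.sqrt(sigma2)
    cc = 0.5 if abs(u1 - mu) >= 0.5 else 0.0
    z = (u1 - mu - math.copysign(cc, u1 - mu)) / sigma if u1 != mu else 0.0

    if n1 * n2 <= EXACT_LIMIT:
        p = _exact_u_pvalue(ranks, n1, u1)
        method = "exact"
    else:
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "asymptotic"
    return GroupTestResult(u_min, u1, float(z), float(p), n1, n2, method)


# ---------------------------------------------------------------------------
# factor-analysis adequacy


def kmo(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Ratio of summed squared correlations to summed squared correlations
    plus summed squared anti-image partial correlations, over the
    off-diagonal.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "correlation matrix is singular; regularize (e.g. smooth to PSD) first"
        ) from None
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d  # anti-image partial correlations
    off = ~np.eye(p, dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    if r2 + q2 == 0:
        return 0.0
    return float(r2 / (r2 + q2))


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        log.warning("Bartlett's test with n (%d) <= p (%d) is unreliable", n, p)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


# ---------------------------------------------------------------------------
# rotations


def varimax(A: np.ndarray, normalize: bool = True, tol: float = 1e-8,
            max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (with Kaiser row normalization).

    Returns (rotated loadings, rotation matrix).
    """
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    h = np.sqrt((A**2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    X = A / h_safe[:, None] if normalize else A.copy()
    T = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = X @ T
        B = X.T @ (L**3 - L * (L**2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        var_new = s.sum()
        if var_new <= var_old * (1 + tol):
            break
        var_old = var_new
    L = X @ T
    if normalize:
        L = L * h_safe[:, None]
    return L, T


def promax(A: np.ndarray, kappa: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Oblique Promax rotation (Hendrickson & White).

    Varimax-rotates ``A``, raises the solution elementwise to power
    ``kappa`` (keeping signs) as the target, and least-squares rotates
    towards it.  Returns (pattern matrix, factor correlation matrix).
    """
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    V, _ = varimax(A)
    target = np.sign(V) * np.abs(V) ** kappa
    # least-squares transformation towards the target
    Q = np.linalg.solve(V.T @ V, V.T @ target)
    # scale columns so implicit factor variances are 1
    d = np.sqrt(np.diag(np.linalg.inv(Q.T @ Q)))
    Q = Q * d
    pattern = V @ Q
    phi = np.linalg.inv(Q.T @ Q)
    # normalize to a proper correlation matrix (guards rounding)
    ds = np.sqrt(np.diag(phi))
    phi = phi / np.outer(ds, ds)
    return pattern, phi


# ---------------------------------------------------------------------------
# principal-axis factoring


@dataclass(frozen=True)
class EFAResult:
    n_items: int
    n_obs: int
    n_factors: int
    eigenvalues: np.ndarray  # of the unreduced correlation matrix
    loadings: np.ndarray  # p x k Promax pattern matrix
    factor_correlations: np.ndarray  # k x k
    communalities: np.ndarray
    variance_explained: float  # proportion of total variance
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_iterations: int
    converged: bool
    heywood: bool
    item_ids: tuple[str, ...] = ()


def _smooth_to_pd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and rescale to a correlation matrix."""
    w, V = np.linalg.eigh(R)
    if w.min() > eps:
        return R
    w = np.clip(w, eps, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def paf_promax(
    data,
    retention: str | int = "kaiser",
    kappa: float = 4.0,
    max_iter: int = 100,
    tol: float = 1e-3,
    item_ids: list[str] | None = None,
) -> EFAResult:
    """Principal-axis factoring with Promax rotation.

    ``data`` is a respondent-by-item matrix (NaN allowed; correlations are
    pairwise-complete).  Communalities start at squared multiple
    correlations and are iterated until the largest change is below
    ``tol``.  Factor count follows the Kaiser rule (eigenvalues of the
    unreduced correlation matrix above 1) unless ``retention`` is an
    integer.  Heywood cases are clipped and flagged.
    """
    if isinstance(data, pd.DataFrame):
        if item_ids is None:
            item_ids = list(data.columns)
        df = data.astype(float)
    else:
        df = pd.DataFrame(np.asarray(data, dtype=float))
    n_obs, p = df.shape
    if item_ids is None:
        item_ids = [str(c) for c in df.columns]
    if n_obs <= p:
        log.warning("fewer observations (%d) than items (%d); EFA will be unstable", n_obs, p)

    constant = [c for c in df.columns if df[c].std(skipna=True) == 0 or df[c].notna().sum() < 2]
    if constant:
        raise ValueError(f"constant or empty items cannot enter EFA: {constant}")

    R = df.corr(method="pearson", min_periods=2).to_numpy()
    if np.isnan(R).any():
        raise ValueError("correlation matrix has missing entries (insufficient overlap)")
    R = _smooth_to_pd(R)

    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    if retention == "kaiser":
        k = int((eigenvalues > 1.0).sum())
        k = max(k, 1)
    else:
        k = int(retention)
        if not 1 <= k <= p:
            raise ValueError(f"retention must be in 1..{p}")

    adequacy_kmo = kmo(R)
    chi2, df_, pval = bartlett_sphericity(R, n_obs)

    # iterated communality estimation, initialized at SMCs
    Rinv = np.linalg.inv(R)
    h = 1.0 - 1.0 / np.diag(Rinv)
    h = np.clip(h, 0.0, 1.0)
    heywood = False
    converged = False
    loadings = np.zeros((p, k))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Rred = R.copy()
        np.fill_diagonal(Rred, h)
        w, V = np.linalg.eigh(Rred)
        idx = np.argsort(w)[::-1][:k]
        wk = np.clip(w[idx], 0.0, None)
        loadings = V[:, idx] * np.sqrt(wk)
        h_new = (loadings**2).sum(axis=1)
        if (h_new > 1.0 + 1e-12).any():
            heywood = True
            h_new = np.clip(h_new, 0.0, 1.0)
        delta = np.abs(h_new - h).max()
        h = h_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("principal-axis factoring did not converge in %d iterations", max_iter)

    variance_explained = float((loadings**2).sum() / p)
    # deterministic sign: largest-magnitude loading per factor positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col

    pattern, phi = promax(loadings, kappa=kappa) if k > 1 else (loadings.copy(), np.eye(1))

    return EFAResult(
        n_items=p,
        n_obs=n_obs,
        n_factors=k,
        eigenvalues=eigenvalues,
        loadings=pattern,
        factor_correlations=phi,
        communalities=h,
        variance_explained=variance_explained,
        kmo=adequacy_kmo,
        bartlett_chi2=chi2,
        bartlett_df=df_,
        bartlett_p=pval,
        n_iterations=n_iter,
        converged=converged,
        heywood=heywood,
        item_ids=tuple(item_ids),
    )
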