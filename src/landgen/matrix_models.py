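"""Distance-matrix regression and multivariate model selection.

Distance matrices are unfolded into pairwise vectors (lower triangle,
row-major). Inference on single matrices uses the Mantel permutation test;
multivariate models use multiple regression on distance matrices (MRM) with
simultaneous row/column permutation of the response matrix. Candidate model
sets are compared by small-sample AIC (AICc) with Akaike weights and a 95%
confidence set, and cross-checked by a maximum-likelihood population effects
(MLPE) mixed model — a random intercept shared by every pair containing the
same population — fitted by REML with a profiled variance ratio.

The AICc sample size is the number of pairwise observations; pairwise
distances are not independent, which is exactly the concern the MLPE stage
addresses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import PairwiseMatrix

__all__ = ["CandidateModel", "MLPEFit", "unfold", "refold", "mantel_test",
           "mrm", "vif", "aicc_select", "mlpe_fit", "pearson_offdiag"]


def unfold(m: PairwiseMatrix) -> np.ndarray:
    """Lower-triangle (i > j) values in row-major order; length n(n-1)/2."""
    return m.values[np.tril_indices(m.n, -1)]


def refold(v: np.ndarray, labels: list[str]) -> PairwiseMatrix:
    n = len(labels)
    M = np.zeros((n, n))
    M[np.tril_indices(n, -1)] = v
    return PairwiseMatrix(list(labels), M + M.T)


@dataclass
class CandidateModel:
    """A named response-plus-predictors bundle of pairwise matrices sharing
    one label order."""

    name: str
    response: PairwiseMatrix
    predictors: dict[str, PairwiseMatrix]
    centered: bool = False

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("at least one predictor required")
        for k, p in self.predictors.items():
            if p.labels != self.response.labels:
                self.predictors[k] = p.reorder(self.response.labels)

    def design(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(y, X with intercept column, predictor names); predictors are
        mean-centered when ``centered`` is set."""
        y = unfold(self.response)
        cols = []
        names = list(self.predictors)
        for k in names:
            v = unfold(self.predictors[k])
            if self.centered:
                v = v - v.mean()
            cols.append(v)
        X = np.column_stack([np.ones_like(y)] + cols)
        return y, X, names


# ---------------------------------------------------------------------------
# Mantel & MRM
# ---------------------------------------------------------------------------

def _perm_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.permutation(n)


def mantel_test(A: PairwiseMatrix, B: PairwiseMatrix, n_perm: int = 10000,
                seed: int | None = None, exact: bool = False) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the unfolded vectors; the null permutes
    rows and columns of B simultaneously. One-tailed (upper) p with the +1
    correction, or the exact fraction over all n! label permutations when
    ``exact`` is set (small n only).
    """
    if A.labels != B.labels:
        B = B.reorder(A.labels)
    a = unfold(A)
    if a.std() == 0 or unfold(B).std() == 0:
        raise ValueError("Mantel r undefined for a constant matrix")
    iu = np.tril_indices(A.n, -1)
    r = float(np.corrcoef(a, B.values[iu])[0, 1])
    if exact:
        import itertools
        hits = total = 0
        for p in itertools.permutations(range(A.n)):
            bp = B.values[np.ix_(p, p)][iu]
            hits += np.corrcoef(a, bp)[0, 1] >= r - 1e-12
            total += 1
        return r, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = _perm_indices(rng, A.n)
        bp = B.values[np.ix_(p, p)][iu]
        hits += np.corrcoef(a, bp)[0, 1] >= r - 1e-12
    return r, (1 + hits) / (n_perm + 1)


@dataclass
class MRMResult:
    coefficients: pd.Series        # intercept + per-predictor slopes
    coef_p: pd.Series              # permutation p (two-tailed on |beta|; NaN intercept)
    r_squared: float
    overall_p: float | None
    n_pairs: int
    sse: float


def _ols(y: np.ndarray, X: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return beta, sse, r2, rank


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the most collinear predictor pair for the error message
        worst, pair = 0.0, (names[0], names[-1])
        for i in range(1, X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                c = abs(np.corrcoef(X[:, i], X[:, j])[0, 1])
                if c > worst:
                    worst, pair = c, (names[i - 1], names[j - 1])
        raise ValueError(f"rank-deficient design: predictors {pair[0]!r} and "
                         f"{pair[1]!r} are collinear (|r| = {worst:.6f})")


def mrm(model: CandidateModel, n_perm: int = 10000,
        seed: int | None = None, exact: bool = False) -> MRMResult:
    """Multiple regression on distance matrices with permutation inference.

    OLS on the unfolded vectors; significance from simultaneous row/column
    permutations of the response matrix with predictors held fixed. The
    overall test uses R^2, coefficient tests are two-tailed on |beta|.
    ``exact`` enumerates all n! permutations instead of sampling.
    """
    y, X, names = model.design()
    _check_rank(X, names)
    beta, sse, r2, _ = _ols(y, X)
    iu = np.tril_indices(model.response.n, -1)
    R = model.response.values

    if exact:
        import itertools
        perms = list(itertools.permutations(range(model.response.n)))
    else:
        rng = np.random.default_rng(seed)
        perms = [_perm_indices(rng, model.response.n) for _ in range(n_perm)]
    hits_r2 = 0
    hits_b = np.zeros(len(beta))
    for p in perms:
        yp = R[np.ix_(p, p)][iu]
        bp, _, r2p, _ = _ols(yp, X)
        hits_r2 += r2p >= r2 - 1e-12
        hits_b += np.abs(bp) >= np.abs(beta) - 1e-12
    if exact:
        overall_p = hits_r2 / len(perms)
        coef_p = hits_b / len(perms)
    elif n_perm:
        overall_p = (1 + hits_r2) / (n_perm + 1)
        coef_p = (1 + hits_b) / (n_perm + 1)
    else:
        overall_p = None
        coef_p = np.full(len(beta), np.nan)
    idx = ["intercept"] + names
    cp = pd.Series(coef_p, index=idx)
    cp["intercept"] = np.nan
    return MRMResult(pd.Series(beta, index=idx), cp, r2, overall_p, len(y), sse)


def vif(model: CandidateModel) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1 - R_j^2) from regressing
    each unfolded predictor on the others (infinite when collinear)."""
    _, X, names = model.design()
    if len(names) < 2:
        raise ValueError("VIF requires at least two predictors")
    out = {}
    for j, name in enumerate(names):
        yj = X[:, j + 1]
        Xo = np.delete(X, j + 1, axis=1)
        _, sse, r2, _ = _ols(yj, Xo)
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# AICc model selection
# ---------------------------------------------------------------------------

def aicc(sse: float, n: int, k: int) -> float:
    """Second-order AIC: n ln(SSE/n) + 2k + 2k(k+1)/(n-k-1); k counts the
    intercept plus slope parameters."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def aicc_select(models: list[CandidateModel], n_perm: int = 10000,
                seed: int | None = None) -> pd.DataFrame:
    """Fit every candidate by MRM and rank by AICc.

    Returns one row per model with coefficients' summary, R^2, overall p,
    max VIF, AICc, delta-AICc, Akaike weight and a 95% confidence-set flag
    (smallest cumulative-weight set >= 0.95, filled in weight order).
    """
    if len(models) > 20:
        raise ValueError("candidate set larger than 20 models")
    ref = models[0].response
    for m in models:
        if m.response.labels != ref.labels or not np.allclose(
                m.response.values, ref.values):
            raise ValueError("all candidates must share the same response")
    rng = np.random.default_rng(seed)
    rows = []
    for m in models:
        fit = mrm(m, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        k = len(m.predictors) + 1
        rows.append({"model": m.name, "k": k, "n": fit.n_pairs, "R2": fit.r_squared,
                     "overall_p": fit.overall_p, "SSE": fit.sse,
                     "AICc": aicc(fit.sse, fit.n_pairs, k),
                     "max_VIF": float(vif(m).max()) if len(m.predictors) > 1 else np.nan,
                     "coefficients": fit.coefficients.to_dict(),
                     "coef_p": fit.coef_p.to_dict()})
    df = pd.DataFrame(rows).set_index("model")
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    rel = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = rel / rel.sum()
    order = df["weight"].sort_values(ascending=False).index
    cum = df.loc[order, "weight"].cumsum()
    in_set = set(order[: int(np.searchsorted(cum.values, 0.95) + 1)])
    df["in_confidence_set"] = [ix in in_set for ix in df.index]
    return df.sort_values("AICc")


# ---------------------------------------------------------------------------
# MLPE mixed model
# ---------------------------------------------------------------------------

@dataclass
class MLPEFit:
    """REML fit of the maximum-likelihood population effects model."""

    beta: pd.Series
    beta_se: pd.Series
    beta_p: pd.Series
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    r2_beta: float
    p_random_effect: float
    phi: float                       # variance ratio sigma2_u / sigma2_e
    converged: bool = True
    trace: list[tuple[float, float]] = field(default_factory=list)


def _pair_incidence(labels: list[str]) -> np.ndarray:
    """(n_pairs, n_pops) matrix with two unit entries per row — one for each
    population in the pair, ordered like :func:`unfold`."""
    n = len(labels)
    rows = []
    for i in range(n):
        for j in range(i):
            z = np.zeros(n)
            z[i] = z[j] = 1.0
            rows.append(z)
    return np.array(rows)


def _reml_neg2(phi: float, y: np.ndarray, X: np.ndarray, ZZt: np.ndarray):
    """-2 REML log-likelihood (up to an additive constant) with the residual
    variance profiled out, plus the pieces needed for downstream inference."""
    n, p = X.shape
    V0 = np.eye(n) + phi * ZZt
    c, low = np.linalg.cholesky(V0), True
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = np.linalg.solve(V0, y)
    Vi_X = np.linalg.solve(V0, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ np.linalg.solve(V0, resid))
    sigma2 = quad / (n - p)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    neg2 = (n - p) * math.log(sigma2) + logdetV + logdetXtViX + (n - p)
    return neg2, beta, sigma2, XtViX


def mlpe_fit(model: CandidateModel, max_phi: float = 1e3,
             tol: float = 1e-10) -> MLPEFit:
    """REML fit of y = X beta + Z u + e on unfolded pairwise distances.

    Z is the pair-to-population incidence matrix (two unit entries per row),
    u ~ N(0, sigma2_u I), e ~ N(0, sigma2_e I). The variance ratio
    phi = sigma2_u / sigma2_e is profiled by bounded scalar optimization;
    predictors are mean-centered (enforced). Wald t tests use residual
    degrees of freedom; the random-effect p comes from a 0.5*chi2(1)
    boundary-mixture likelihood-ratio test; R2_beta derives from the Wald F
    of the non-intercept fixed effects.
    """
    if not model.centered:
        model = CandidateModel(model.name, model.response,
                               dict(model.predictors), centered=True)
    y, X, names = model.design()
    _check_rank(X, names)
    Z = _pair_incidence(model.response.labels)
    ZZt = Z @ Z.T
    n, p = X.shape

    trace: list[tuple[float, float]] = []

    def obj(phi: float) -> float:
        val = _reml_neg2(phi, y, X, ZZt)[0]
        trace.append((phi, val))
        return val

    res = optimize.minimize_scalar(obj, bounds=(0.0, max_phi), method="bounded",
                                   options={"xatol": tol})
    if not res.success:
        raise RuntimeError(f"MLPE REML optimization failed: {res.message}; trace={trace[-5:]}")
    phi = float(res.x)
    if obj(0.0) <= res.fun:       # boundary solution
        phi = 0.0
    neg2_hat, beta, sigma2, XtViX = _reml_neg2(phi, y, X, ZZt)
    neg2_null = _reml_neg2(0.0, y, X, ZZt)[0]
    lr = max(0.0, neg2_null - neg2_hat)
    p_re = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 1.0

    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    df_res = n - p
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_res)

    # Wald F over the q non-intercept fixed effects -> R2_beta = qF/(qF + df)
    q = p - 1
    if q > 0:
        b1 = beta[1:]
        c11 = cov[1:, 1:]
        F = float(b1 @ np.linalg.solve(c11, b1)) / q
        r2b = q * F / (q * F + df_res)
    else:
        r2b = 0.0

    idx = ["intercept"] + names
    return MLPEFit(pd.Series(beta, index=idx), pd.Series(se, index=idx),
                   pd.Series(pvals, index=idx), float(phi * sigma2),
                   float(sigma2), -0.5 * neg2_hat, float(r2b), float(p_re),
                   phi, True, trace)


def pearson_offdiag(A: PairwiseMatrix, B: PairwiseMatrix) -> float:
    """Pearson correlation of the unfolded off-diagonal vectors."""
    if A.labels != B.labels:
        B = B.reorder(A.labels)
    a, b = unfold(A), unfold(B)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant matrix")
    return float(np.corrcoef(a, b)[0, 1])
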