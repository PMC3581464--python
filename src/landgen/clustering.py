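"""Bayesian admixture clustering and cluster-number heuristics.

A Gibbs sampler for the admixture model with uncorrelated allele frequencies:
each gene copy carries a latent cluster assignment z, cluster allele
frequencies have a flat Dirichlet prior, individual admixture proportions q a
symmetric Dirichlet(alpha) prior, and alpha is updated by a Metropolis step
on log alpha with a Uniform(0, 10) prior. Model choice uses the penalized
log-evidence estimate mean(lnL) - var(lnL)/2 and the second-order rate-of-
change statistic (delta-K) over replicate runs. Also provides cluster-label
alignment across runs and individual-based barrier Mantel tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_formats import MISSING, GenotypeTable

__all__ = ["ClusterRun", "run_admixture", "evanno_delta_k", "align_runs",
           "shared_allele_distance", "barrier_mantel", "plot_admixture"]


@dataclass
class ClusterRun:
    """One MCMC run at a fixed K: posterior-mean admixture (Q), posterior-mean
    cluster allele frequencies (P, per locus), the log-likelihood trace and
    the penalized log-evidence estimate."""

    K: int
    Q: np.ndarray                       # (n_ind, K)
    P: list[np.ndarray]                 # per locus (K, n_alleles)
    lnL_trace: np.ndarray
    ln_prob_K: float
    alpha_trace: np.ndarray
    seed: int | None
    individuals: list[str] = field(default_factory=list)
    allele_codes: list[np.ndarray] = field(default_factory=list)


def _encode(gt: GenotypeTable) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per locus: observed-allele code array (n_ind, 2) with -1 missing, and
    the sorted allele identifiers backing the codes."""
    coded, alphabets = [], []
    for li in range(gt.n_loci):
        calls = gt.calls[:, li]
        alleles = np.unique(calls[calls != MISSING])
        code = {a: i for i, a in enumerate(alleles)}
        arr = np.full(calls.shape, -1, dtype=np.int64)
        for a, i in code.items():
            arr[calls == a] = i
        coded.append(arr)
        alphabets.append(alleles)
    return coded, alphabets


def run_admixture(gt: GenotypeTable, K: int, burnin: int = 30000,
                  iters: int = 100000, seed: int | None = None,
                  alpha0: float = 1.0) -> ClusterRun:
    """Gibbs sampler for the admixture model at a fixed cluster count K.

    Sweeps: (1) latent cluster of every observed gene copy given q and p,
    (2) cluster allele frequencies p | z ~ Dirichlet(1 + counts),
    (3) admixture q_i | z ~ Dirichlet(alpha + counts), (4) Metropolis update
    of the common alpha. The log-likelihood ln P(X | q, p) is recorded every
    post-burn-in sweep; ln_prob_K = mean(lnL) - var(lnL)/2.
    """
    n = gt.n_individuals
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of individuals ({n})")
    rng = np.random.default_rng(seed)
    coded, alphabets = _encode(gt)
    L = gt.n_loci
    obs_mask = [c >= 0 for c in coded]           # (n, 2) per locus
    safe = [np.where(c >= 0, c, 0) for c in coded]

    q = np.full((n, K), 1.0 / K)
    p = [rng.dirichlet(np.ones(len(a)), size=K) for a in alphabets]
    alpha = float(alpha0)

    q_sum = np.zeros_like(q)
    p_sum = [np.zeros_like(pl) for pl in p]
    lnl_rec = np.empty(iters)
    alpha_rec = np.empty(iters)
    ln10 = math.log(10.0)

    for sweep in range(burnin + iters):
        z_counts_ind = np.zeros((n, K))
        lnl = 0.0
        new_p_counts = [np.ones_like(pl) for pl in p]  # Dirichlet(1) prior
        for li in range(L):
            a_idx = safe[li]                       # (n, 2)
            mask = obs_mask[li]
            # per copy: unnormalized P(z=k) = q[i,k] * p[k, allele]
            w = q[:, None, :] * p[li].T[a_idx]     # (n, 2, K)
            tot = w.sum(axis=2)
            with np.errstate(divide="ignore"):
                lnl += float(np.where(mask, np.log(tot), 0.0).sum())
            # categorical draw via inverse CDF
            cdf = np.cumsum(w, axis=2)
            u = rng.random((n, 2)) * tot
            z = (u[:, :, None] > cdf).sum(axis=2)  # (n, 2) in 0..K-1
            zm = np.where(mask, z, -1)
            for k in range(K):
                sel = zm == k
                z_counts_ind[:, k] += sel.sum(axis=1)
                np.add.at(new_p_counts[li][k], a_idx[sel], 1.0)
        # p | z
        for li in range(L):
            g = rng.gamma(new_p_counts[li])
            p[li] = g / g.sum(axis=1, keepdims=True)
        # q | z
        g = rng.gamma(alpha + z_counts_ind)
        g_tot = g.sum(axis=1, keepdims=True)
        g_tot[g_tot == 0] = 1.0
        q = g / g_tot
        q = np.clip(q, 1e-300, None)
        q /= q.sum(axis=1, keepdims=True)
        # alpha | q  (symmetric Metropolis on log alpha, Uniform(0,10) prior)
        if K > 1:
            prop = alpha * math.exp(rng.normal(0.0, 0.3))
            if 0.0 < prop < 10.0:
                lq = np.log(q).sum()

                def log_post(a: float) -> float:
                    return n * (math.lgamma(K * a) - K * math.lgamma(a)) + (a - 1.0) * lq

                # Jacobian of the log-scale proposal: + log(prop/alpha)
                log_acc = log_post(prop) - log_post(alpha) + math.log(prop / alpha)
                if math.log(rng.random()) < log_acc:
                    alpha = prop
        if sweep >= burnin:
            t = sweep - burnin
            lnl_rec[t] = lnl
            alpha_rec[t] = alpha
            q_sum += q
            for li in range(L):
                p_sum[li] += p[li]

    Q = q_sum / iters
    P = [ps / iters for ps in p_sum]
    ln_prob_K = float(lnl_rec.mean() - lnl_rec.var(ddof=0) / 2.0)
    return ClusterRun(K, Q, P, lnl_rec, ln_prob_K, alpha_rec, seed,
                      list(gt.individuals), alphabets)


def log_evidence_k1(gt: GenotypeTable) -> float:
    """Closed-form log model evidence at K=1 with Dirichlet(1) frequency
    priors: the product over loci of multinomial-Dirichlet marginals of the
    pooled allele counts."""
    total = 0.0
    for li in range(gt.n_loci):
        calls = gt.calls[:, li]
        typed = calls[calls != MISSING]
        alleles, counts = np.unique(typed, return_counts=True)
        k = len(alleles)
        N = counts.sum()
        total += (math.lgamma(k) - math.lgamma(k + N)
                  + sum(math.lgamma(1 + c) for c in counts))
    return total


def evanno_delta_k(runs: list[ClusterRun]) -> pd.DataFrame:
    """Second-order rate-of-change statistic over replicate runs grouped by K.

    delta_K(K) = mean|L(K+1) - 2 L(K) + L(K-1)| / SD(L(K)); defined for
    interior K only and flagged infinite when the replicate SD is zero.
    Requires at least three consecutive K values with >= 2 replicates each.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.ln_prob_K)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicate runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        row = {"K": k, "n_runs": len(by_k[k]), "mean_lnP": mean[k], "sd_lnP": sd[k],
               "abs_L2": np.nan, "delta_K": np.nan}
        if ks[0] < k < ks[-1]:
            l2 = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            row["abs_L2"] = l2
            row["delta_K"] = l2 / sd[k] if sd[k] > 0 else math.inf
        rows.append(row)
    return pd.DataFrame(rows).set_index("K")


def align_runs(runs: list[ClusterRun], reference: ClusterRun) -> list[np.ndarray]:
    """Permute cluster labels of each run to best match a reference run.

    The Frobenius-optimal label permutation is found exactly as a linear
    assignment over column pair distances. Returns the aligned Q matrices.
    """
    out = []
    for run in runs:
        if run.K != reference.K:
            raise ValueError("runs must share the same K")
        if run.Q.shape != reference.Q.shape:
            raise ValueError("runs must share the same individuals")
        K = run.K
        cost = np.empty((K, K))
        for a in range(K):
            for b in range(K):
                cost[a, b] = ((run.Q[:, a] - reference.Q[:, b]) ** 2).sum()
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows
        out.append(run.Q[:, perm])
    return out


def plot_admixture(run: ClusterRun, path, populations: list[str] | None = None):
    """Stacked-bar admixture plot (one bar per individual, one colour per
    cluster), optionally grouped by population label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Q = run.Q
    order = np.arange(Q.shape[0])
    if populations is not None:
        order = np.argsort(populations, kind="stable")
    fig, ax = plt.subplots(figsize=(max(6, Q.shape[0] / 12), 2.5))
    bottom = np.zeros(Q.shape[0])
    for k in range(run.K):
        vals = Q[order, k]
        ax.bar(np.arange(Q.shape[0]), vals, bottom=bottom, width=1.0)
        bottom += vals
    ax.set_xlim(-0.5, Q.shape[0] - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# individual-based barrier tests
# ---------------------------------------------------------------------------

def shared_allele_distance(gt: GenotypeTable) -> np.ndarray:
    """1 - proportion of shared alleles, averaged over loci typed in both
    individuals. Genotype pairs share 0, 1 or 2 alleles (count-aware)."""
    n = gt.n_individuals
    D = np.zeros((n, n))
    calls = gt.calls
    typed = calls[:, :, 0] != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = typed[i] & typed[j]
            if not both.any():
                D[i, j] = D[j, i] = np.nan
                continue
            ps = 0.0
            for li in np.nonzero(both)[0]:
                a = calls[i, li]
                b = list(calls[j, li])
                shared = 0
                for x in a:
                    if x in b:
                        shared += 1
                        b.remove(x)
                ps += shared / 2.0
            d = 1.0 - ps / both.sum()
            D[i, j] = D[j, i] = d
    return D


def barrier_mantel(gt: GenotypeTable, side_labels: list[str],
                   n_perm: int = 10000, seed: int | None = None) -> tuple[float, float]:
    """Mantel test of a putative linear barrier at the individual level.

    Correlates the shared-allele genetic distance with a binary model matrix
    (0 same side, 1 opposite sides) and permutes individuals. One-tailed
    (upper) p with the +1 correction.
    """
    if len(side_labels) != gt.n_individuals:
        raise ValueError("one side label per individual required")
    sides = np.asarray(side_labels)
    uniq = np.unique(sides)
    if len(uniq) != 2 or min((sides == u).sum() for u in uniq) < 2:
        raise ValueError("need exactly two sides with >= 2 individuals each")
    G = shared_allele_distance(gt)
    B = (sides[:, None] != sides[None, :]).astype(float)
    iu = np.tril_indices(len(sides), -1)
    g = G[iu]
    keep = ~np.isnan(g)
    rng = np.random.default_rng(seed)

    def corr(model: np.ndarray) -> float:
        b = model[iu][keep]
        gv = g[keep]
        if b.std() == 0 or gv.std() == 0:
            raise ValueError("constant matrix in barrier test")
        return float(np.corrcoef(gv, b)[0, 1])

    r = corr(B)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(sides))
        hits += corr(B[np.ix_(perm, perm)]) >= r - 1e-12
    return r, (1 + hits) / (n_perm + 1)
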