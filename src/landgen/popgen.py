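"""Diversity and differentiation statistics for diploid microsatellite data.

Implements per-site diversity (observed/unbiased expected heterozygosity,
allele counts, rarefied allelic richness), the Hardy–Weinberg exact test via
a Markov chain over genotype tables with fixed allele counts, a genotypic
linkage-disequilibrium permutation test, Weir & Cockerham's variance-component
theta with permutation significance, Jost's D with harmonic-mean combination
over loci, multiple-testing adjustment and small regression helpers.

Missing genotypes are excluded pairwise per locus throughout, so per-site
sample sizes are fractional when averaged over loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeTable, PairwiseMatrix, PointSet

__all__ = [
    "DiversityTable", "DifferentiationResult", "diversity", "hwe_exact_test",
    "ld_test", "weir_cockerham_fst", "jost_d", "adjust_pvalues", "linearize",
    "elevation_diversity_regression",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pop_locus_counts(gt: GenotypeTable, pop: str, locus_i: int) -> dict[int, int]:
    """Allele -> count of gene copies among typed individuals."""
    idx = gt.pop_indices(pop)
    calls = gt.calls[idx, locus_i]  # (n, 2)
    typed = calls[calls[:, 0] != MISSING]
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g gene copies.

    A_g = sum_a [1 - C(N - N_a, g) / C(N, g)], evaluated as an exact product
    to avoid factorial overflow.
    """
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds available genes N={N}")
    out = 0.0
    for Na in counts:
        M = N - int(Na)
        if M < g:
            out += 1.0
            continue
        ratio = 1.0
        for j in range(g):
            ratio *= (M - j) / (N - j)
        out += 1.0 - ratio
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Per-population (and per locus x population) diversity summary."""

    per_population: pd.DataFrame   # index pop: n, n_msat, H_O, H_E, A, A_g
    per_locus: pd.DataFrame        # index (pop, locus): n_typed, H_O, H_E, A, A_g
    g: int
    flagged_loci: list[tuple[str, str, int]] = field(default_factory=list)
    """(population, locus, g_used) where fewer than ``g`` genes forced a
    smaller rarefaction size."""


def diversity(gt: GenotypeTable, g: int | None = None) -> DiversityTable:
    """Observed/unbiased expected heterozygosity, allele counts and rarefied
    allelic richness per population.

    ``g`` is the rarefaction gene count; the default is twice the smallest
    population sample (the standardized-subsample convention). H_E uses the
    small-sample correction 2n/(2n-1) on the gene diversity 1 - sum p^2 with
    n the number of typed diploids at the locus. Population-level H_O and H_E
    average over loci; A and A_g sum over loci.
    """
    pops = gt.pop_names()
    if g is None:
        g = 2 * min(gt.n_per_pop().values())
    # minimum typed gene count per locus across populations, for the fallback
    min_genes = {}
    for li, locus in enumerate(gt.loci):
        gene_counts = []
        for p in pops:
            idx = gt.pop_indices(p)
            calls = gt.calls[idx, li]
            gene_counts.append(2 * int((calls[:, 0] != MISSING).sum()))
        min_genes[locus] = min(gene_counts)

    flagged: list[tuple[str, str, int]] = []
    rows = []
    for p in pops:
        idx = gt.pop_indices(p)
        for li, locus in enumerate(gt.loci):
            calls = gt.calls[idx, li]
            typed = calls[calls[:, 0] != MISSING]
            n_typed = len(typed)
            if n_typed == 0:
                warnings.warn(f"population {p} has no typed individuals at {locus}; skipped")
                continue
            alleles, counts = np.unique(typed.ravel(), return_counts=True)
            freqs = counts / counts.sum()
            h_o = float((typed[:, 0] != typed[:, 1]).mean())
            gene_div = 1.0 - float((freqs ** 2).sum())
            n_genes = 2 * n_typed
            h_e = gene_div * n_genes / (n_genes - 1) if n_genes > 1 else 0.0
            g_use = g
            if n_genes < g:
                g_use = min(g, min_genes[locus], n_genes)
                flagged.append((p, locus, g_use))
            a_g = _rarefied_richness(counts, g_use)
            rows.append({"population": p, "locus": locus, "n_typed": n_typed,
                         "H_O": h_o, "H_E": h_e, "A": len(alleles), "A_g": a_g})
    per_locus = pd.DataFrame(rows).set_index(["population", "locus"])

    agg = []
    n_per = gt.n_per_pop()
    n_msat = gt.n_msat()
    for p in pops:
        sub = per_locus.loc[p]
        agg.append({"population": p, "n": n_per[p], "n_msat": n_msat[p],
                    "H_O": sub["H_O"].mean(), "H_E": sub["H_E"].mean(),
                    "A": int(sub["A"].sum()), "A_g": sub["A_g"].sum()})
    per_population = pd.DataFrame(agg).set_index("population")
    return DiversityTable(per_population, per_locus, g, flagged)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Markov chain)
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    p_value: float | None
    se: float | None
    defined: bool
    reason: str = ""


def _table_logprob_stat(geno_counts: np.ndarray, lgamma_cache: np.ndarray) -> float:
    """Ordering statistic proportional to the conditional log-probability of a
    genotype-count table given its allele counts: h*ln2 - sum ln(n_ij!)."""
    k = geno_counts.shape[0]
    h = 0
    s = 0.0
    for i in range(k):
        for j in range(i, k):
            c = geno_counts[i, j]
            if c:
                s += lgamma_cache[c]
                if i != j:
                    h += c
    return h * math.log(2.0) - s


def hwe_exact_test(gt: GenotypeTable, locus: str, population: str,
                   batches: int = 100, iters_per_batch: int = 1000,
                   seed: int | None = None, burnin: int = 1000) -> HWEResult:
    """Exact-test p-value for Hardy–Weinberg proportions by Markov chain.

    The chain walks over genotype tables with the observed allele counts
    held fixed, by repeatedly swapping gene copies between genotypes — a
    symmetric move on pairings of the 2n gene copies whose stationary law is
    the exact conditional (HWE) distribution of tables. The reported p is the
    chain frequency of tables no more probable than the observed one (the
    probability test), with a standard error from batch means.
    """
    li = gt.loci.index(locus)
    idx = gt.pop_indices(population)
    calls = gt.calls[idx, li]
    typed = calls[calls[:, 0] != MISSING]
    alleles = np.unique(typed.ravel())
    if len(alleles) < 2:
        return HWEResult(None, None, False, "monomorphic locus")
    code = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    # flat vector of 2n gene copies; pairs (2i, 2i+1) are genotypes
    genes = np.array([code[a] for pair in typed for a in pair], dtype=np.int64)
    n2 = len(genes)

    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(0, n2, 2):
        a, b = sorted((genes[i], genes[i + 1]))
        counts[a, b] += 1
    lg = np.array([math.lgamma(c + 1) for c in range(n2 + 1)])
    obs_stat = _table_logprob_stat(counts, lg)

    rng = np.random.default_rng(seed)
    stat = obs_stat
    total = burnin + batches * iters_per_batch
    # pre-draw the random stream in blocks for speed
    us = rng.integers(0, n2, size=total)
    vs = rng.integers(0, n2, size=total)
    batch_hits = np.zeros(batches)
    it = 0
    for step in range(total):
        u, v = us[step], vs[step]
        if u // 2 != v // 2 and genes[u] != genes[v]:
            pu, pv = u ^ 1, v ^ 1  # partners
            g1 = tuple(sorted((genes[u], genes[pu])))
            g2 = tuple(sorted((genes[v], genes[pv])))
            counts[g1] -= 1
            counts[g2] -= 1
            genes[u], genes[v] = genes[v], genes[u]
            g1n = tuple(sorted((genes[u], genes[pu])))
            g2n = tuple(sorted((genes[v], genes[pv])))
            counts[g1n] += 1
            counts[g2n] += 1
            stat = _table_logprob_stat(counts, lg)
        if step >= burnin:
            b = (step - burnin) // iters_per_batch
            batch_hits[b] += stat <= obs_stat + 1e-9
    batch_means = batch_hits / iters_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else None
    return HWEResult(p, se, True)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    per_population: pd.DataFrame  # pop, G, p, defined
    combined_p: float | None


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G on a contingency table (0 cells contribute 0)."""
    total = table.sum()
    if total == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _geno_codes(calls: np.ndarray) -> np.ndarray:
    """Encode unordered genotype pairs as small integers; MISSING -> -1."""
    lo = np.minimum(calls[:, 0], calls[:, 1])
    hi = np.maximum(calls[:, 0], calls[:, 1])
    key = lo * 10000 + hi
    key[calls[:, 0] == MISSING] = -1
    uniq = np.unique(key[key >= 0])
    code = {u: i for i, u in enumerate(uniq)}
    return np.array([code.get(x, -1) for x in key], dtype=np.int64)


def ld_test(gt: GenotypeTable, locus_a: str, locus_b: str,
            n_perm: int = 1000, seed: int | None = None) -> LDResult:
    """Genotypic linkage-disequilibrium test per population.

    G statistic on the two-locus genotype contingency table; the null is
    generated by permuting one locus's genotypes among individuals within the
    population. Population p-values are combined by Fisher's method.
    """
    la, lb = gt.loci.index(locus_a), gt.loci.index(locus_b)
    rng = np.random.default_rng(seed)
    rows = []
    pvals = []
    for pop in gt.pop_names():
        idx = gt.pop_indices(pop)
        ca = _geno_codes(gt.calls[idx, la])
        cb = _geno_codes(gt.calls[idx, lb])
        keep = (ca >= 0) & (cb >= 0)
        ca, cb = ca[keep], cb[keep]
        if len(np.unique(ca)) < 2 or len(np.unique(cb)) < 2:
            rows.append({"population": pop, "G": np.nan, "p": np.nan, "defined": False})
            continue
        na, nb = ca.max() + 1, cb.max() + 1
        obs_tab = np.zeros((na, nb))
        np.add.at(obs_tab, (ca, cb), 1)
        g_obs = _g_statistic(obs_tab)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(cb)
            tab = np.zeros((na, nb))
            np.add.at(tab, (ca, perm), 1)
            hits += _g_statistic(tab) >= g_obs - 1e-12
        p = (1 + hits) / (n_perm + 1)
        rows.append({"population": pop, "G": g_obs, "p": p, "defined": True})
        pvals.append(p)
    combined = None
    if pvals:
        x2 = -2.0 * np.log(pvals).sum()
        combined = float(stats.chi2.sf(x2, 2 * len(pvals)))
    return LDResult(pd.DataFrame(rows), combined)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_locus_components(pop_calls: list[np.ndarray]) -> tuple[float, float, float]:
    """Sum of the a, b, c variance components over alleles at one locus.

    ``pop_calls``: per population, the (n_i, 2) typed calls. Components follow
    the weighted analysis of variance with unequal sample sizes and observed
    heterozygote frequencies.
    """
    pops = [c for c in pop_calls if len(c) > 0]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(c) for c in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([(c == al).sum() / (2 * len(c)) for c in pops])
        h_i = np.array([((c[:, 0] == al) ^ (c[:, 1] == al)).mean() for c in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def _theta_multilocus(gt: GenotypeTable, pops: list[str]) -> float:
    num = den = 0.0
    for li in range(gt.n_loci):
        pop_calls = []
        for p in pops:
            idx = gt.pop_indices(p)
            calls = gt.calls[idx, li]
            pop_calls.append(calls[calls[:, 0] != MISSING])
        a, b, c = _wc_locus_components(pop_calls)
        num += a
        den += a + b + c
    return num / den if den != 0 else 0.0


@dataclass
class DifferentiationResult:
    """Global and pairwise differentiation with permutation significance."""

    theta_global: float | None = None
    theta_global_p: float | None = None
    theta_pairwise: PairwiseMatrix | None = None
    p_pairwise: PairwiseMatrix | None = None
    d_est_global: float | None = None
    d_est_pairwise: PairwiseMatrix | None = None
    per_locus: pd.DataFrame | None = None
    flagged_loci: list[str] = field(default_factory=list)


def weir_cockerham_fst(gt: GenotypeTable, populations: list[str] | None = None,
                       n_perm: int = 0, seed: int | None = None,
                       pairwise: bool = True) -> DifferentiationResult:
    """Multilocus Weir–Cockerham theta, globally and per population pair.

    Significance permutes individuals among populations: across all
    populations for the global value, between the two members for each pair.
    Permutation p-values use the +1 correction. Loci monomorphic across the
    subset contribute zero components.
    """
    pops = populations or gt.pop_names()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    sub = gt.subset(populations=pops)
    rng = np.random.default_rng(seed)

    def permuted_theta(table: GenotypeTable, plist: list[str]) -> float:
        shuffled = list(table.populations)
        rng.shuffle(shuffled)
        perm = GenotypeTable(table.individuals, shuffled, table.loci, table.calls)
        return _theta_multilocus(perm, plist)

    theta = _theta_multilocus(sub, pops)
    theta_p = None
    if n_perm > 0:
        hits = sum(permuted_theta(sub, pops) >= theta - 1e-12 for _ in range(n_perm))
        theta_p = (1 + hits) / (n_perm + 1)

    per_locus_rows = []
    for li, locus in enumerate(sub.loci):
        pop_calls = []
        for p in pops:
            idx = sub.pop_indices(p)
            calls = sub.calls[idx, li]
            pop_calls.append(calls[calls[:, 0] != MISSING])
        a, b, c = _wc_locus_components(pop_calls)
        per_locus_rows.append({"locus": locus, "a": a, "b": b, "c": c,
                               "theta": a / (a + b + c) if (a + b + c) != 0 else np.nan})
    per_locus = pd.DataFrame(per_locus_rows).set_index("locus")

    theta_pw = p_pw = None
    if pairwise:
        n = len(pops)
        T = np.zeros((n, n))
        P = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pair = gt.subset(populations=[pops[i], pops[j]])
                t = _theta_multilocus(pair, [pops[i], pops[j]])
                T[i, j] = T[j, i] = t
                if n_perm > 0:
                    hits = sum(permuted_theta(pair, [pops[i], pops[j]]) >= t - 1e-12
                               for _ in range(n_perm))
                    P[i, j] = P[j, i] = (1 + hits) / (n_perm + 1)
        theta_pw = PairwiseMatrix(list(pops), T)
        p_pw = PairwiseMatrix(list(pops), P) if n_perm > 0 else None

    return DifferentiationResult(theta_global=theta, theta_global_p=theta_p,
                                 theta_pairwise=theta_pw, p_pairwise=p_pw,
                                 per_locus=per_locus)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

D_EST_FLOOR = 1e-6  # substituted for nonpositive per-locus values in harmonic means


def _jost_d_locus(pop_calls: list[np.ndarray]) -> float | None:
    """Nearly unbiased D for one locus over k populations.

    Uses the sample-size-corrected heterozygosity estimators
    Hs_est = (2ñ/(2ñ-1)) Hs and Ht_est = Ht + Hs_est/(2ñk) with ñ the
    harmonic mean of typed diploids, then D = (k/(k-1)) (Ht-Hs)/(1-Hs).
    Returns None when fewer than two populations are typed.
    """
    pops = [c for c in pop_calls if len(c) > 0]
    k = len(pops)
    if k < 2:
        return None
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    freqs = np.array([[np.mean(c.ravel() == al) for al in alleles] for c in pops])
    n_i = np.array([len(c) for c in pops], dtype=float)
    n_harm = k / (1.0 / n_i).sum()
    hs = 1.0 - float((freqs ** 2).sum(axis=1).mean())
    pbar = freqs.mean(axis=0)
    ht = 1.0 - float((pbar ** 2).sum())
    hs_est = hs * 2 * n_harm / (2 * n_harm - 1)
    ht_est = ht + hs_est / (2 * n_harm * k)
    if hs_est >= 1.0:
        return None
    return (ht_est - hs_est) / (1.0 - hs_est) * k / (k - 1)


def _harmonic_mean_d(values: list[float]) -> tuple[float, list[int]]:
    """Harmonic mean across loci; nonpositive entries floored and flagged."""
    flagged = [i for i, v in enumerate(values) if v <= 0]
    adj = np.array([max(v, D_EST_FLOOR) for v in values])
    return float(len(adj) / (1.0 / adj).sum()), flagged


def jost_d(gt: GenotypeTable, populations: list[str] | None = None) -> DifferentiationResult:
    """Jost's D per population pair and globally, combined over loci by the
    harmonic mean (nonpositive per-locus values floored at 1e-6 and flagged)."""
    pops = populations or gt.pop_names()
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    def calls_by_pop(plist: list[str], li: int) -> list[np.ndarray]:
        out = []
        for p in plist:
            idx = gt.pop_indices(p)
            calls = gt.calls[idx, li]
            out.append(calls[calls[:, 0] != MISSING])
        return out

    per_locus_d = []
    locus_names = []
    for li, locus in enumerate(gt.loci):
        d = _jost_d_locus(calls_by_pop(pops, li))
        if d is not None:
            per_locus_d.append(d)
            locus_names.append(locus)
    flagged: list[str] = []
    d_global, flag_idx = _harmonic_mean_d(per_locus_d)
    flagged.extend(locus_names[i] for i in flag_idx)

    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dvals = []
            for li in range(gt.n_loci):
                d = _jost_d_locus(calls_by_pop([pops[i], pops[j]], li))
                if d is not None:
                    dvals.append(d)
            dm, _ = _harmonic_mean_d(dvals)
            D[i, j] = D[j, i] = dm
    per_locus = pd.DataFrame({"locus": locus_names, "D_est": per_locus_d}).set_index("locus")
    return DifferentiationResult(d_est_global=d_global,
                                 d_est_pairwise=PairwiseMatrix(list(pops), D),
                                 per_locus=per_locus, flagged_loci=flagged)


# ---------------------------------------------------------------------------
# multiple testing, linearization, regression
# ---------------------------------------------------------------------------

def adjust_pvalues(pvals, method: str = "fdr", alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up or Bonferroni adjustment.

    Returns a table with raw and adjusted p-values, rejection flags and, for
    Bonferroni, the per-test threshold alpha/m (attribute ``threshold`` on
    the returned frame's ``attrs``).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method.lower() in ("fdr", "bh"):
        adjusted = stats.false_discovery_control(p, method="bh")
        rejected = adjusted <= alpha
        tag, threshold = "FDR", None
    elif method.lower() == "bonferroni":
        adjusted = np.minimum(p * m, 1.0)
        threshold = alpha / m
        rejected = p < threshold
        tag = "Bonferroni"
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame({"raw_p": p, "adjusted_p": adjusted,
                       "rejected": rejected, "method": tag})
    df.attrs["threshold"] = threshold
    df.attrs["alpha"] = alpha
    return df


def linearize(m: PairwiseMatrix) -> PairwiseMatrix:
    """Element-wise d/(1-d); negative inputs are clamped to 0 first."""
    off = ~np.eye(m.n, dtype=bool)
    if (m.values[off] >= 1.0).any():
        raise ValueError("linearization requires all off-diagonal values < 1")
    v = np.clip(m.values, 0.0, None)
    out = v / (1.0 - v)
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(list(m.labels), out)


def elevation_diversity_regression(richness, elevation=None,
                                   pts: PointSet | None = None):
    """OLS of allelic richness on elevation; returns (slope, intercept, R^2, p).

    ``richness`` may be a DiversityTable (A_g column used), a mapping or an
    array; elevations come from ``elevation`` or ``pts.elevations``.
    """
    if isinstance(richness, DiversityTable):
        y = richness.per_population["A_g"].to_numpy(float)
    else:
        y = np.asarray(richness, dtype=float)
    if elevation is None:
        if pts is None or pts.elevations is None:
            raise ValueError("elevations required")
        x = pts.elevations
    else:
        x = np.asarray(elevation, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three populations")
    if np.ptp(x) == 0:
        raise ValueError("constant elevation")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2, res.pvalue
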