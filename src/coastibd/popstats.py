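"""Descriptive statistics and Weir–Cockerham F-statistics with permutation
inference.

Implements the classical toolbox for codominant microsatellite data:

* Nei's unbiased expected heterozygosity and observed heterozygosity,
* allelic richness by Hurlbert rarefaction (in units of genes, ``2g``),
* Weir & Cockerham (1984) variance-component estimators of F_IS, F_ST and
  F_IT (theta may be negative; multilocus values are ratios of summed
  components, not means of ratios),
* permutation tests: F_ST (genotypes permuted among populations, theta or
  log-likelihood G statistic), Hardy–Weinberg (alleles permuted within
  population and locus, statistic F_IS), and genotypic disequilibrium
  (single-locus genotypes permuted among individuals within population,
  statistic two-locus G),
* Benjamini–Hochberg step-up control of the false discovery rate per test
  family.

Missing data are handled pairwise-complete per locus: an individual missing
at one locus still contributes at every other locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .genotypes import GenotypeMatrix

__all__ = [
    "FstResult",
    "diversity_summary",
    "hurlbert_rarefaction",
    "wc_components",
    "wc_fstats",
    "pairwise_fst",
    "g_statistic",
    "permutation_fst_test",
    "hwe_test",
    "ld_test",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# diversity

def _allele_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, cnts = np.unique(alleles, return_counts=True)
    return vals, cnts


def hurlbert_rarefaction(counts: np.ndarray, k: int) -> float:
    """Expected number of distinct alleles in a sample of ``k`` genes.

    ``counts`` are the observed allele counts (genes) at one locus in one
    population.  Uses the hypergeometric expectation
    ``sum_i 1 - C(N - n_i, k) / C(N, k)`` computed in log space.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_genes = int(counts.sum())
    if k > n_genes:
        raise ValueError(f"rarefaction size {k} exceeds sample of {n_genes} genes")
    if k == n_genes:
        return float(len(counts))

    def log_comb(n: int, r: int) -> float:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    total = 0.0
    for n_i in counts:
        if n_genes - n_i < k:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(n_genes - n_i, k) - log_comb(n_genes, k))
    return float(total)


def diversity_summary(
    gm: GenotypeMatrix,
    rarefaction_size: int | None = None,
) -> pd.DataFrame:
    """Per-locus, per-population diversity table.

    Columns: ``Ho`` (fraction heterozygous), ``He`` (Nei unbiased,
    ``2n/(2n-1) * (1 - sum p_i^2)``), ``Fis_wc`` (Weir–Cockerham f from
    variance components, the default convention), ``Fis_nei``
    (``1 - Ho/He``), ``Ar`` (allelic richness rarefied to ``2g`` genes),
    ``An`` (observed allele count), ``n`` (genotyped individuals).

    ``rarefaction_size`` is the number of diploid individuals ``g``; the
    default is the smallest per-population genotyped count at each locus.
    Monomorphic cells have ``He = Ho = 0`` and F_IS reported as NaN.
    Cells with no genotyped individuals are flagged with ``n = 0`` and NaN
    statistics rather than zeros.
    """
    rows = []
    pops = gm.pop_names
    for j, locus in enumerate(gm.loci):
        per_pop: dict[str, np.ndarray] = {}
        for pop in pops:
            idx = gm.pop_indices(pop)
            g = gm.calls[idx, j, :]
            per_pop[pop] = g[(g != 0).all(axis=1)]
        counts = [len(g) for g in per_pop.values() if len(g) > 0]
        g_default = min(counts) if counts else 0
        g_use = rarefaction_size if rarefaction_size is not None else g_default

        for pop in pops:
            g = per_pop[pop]
            n = len(g)
            if n == 0:
                rows.append(
                    dict(locus=locus, population=pop, n=0, Ho=np.nan, He=np.nan,
                         Fis_wc=np.nan, Fis_nei=np.nan, Ar=np.nan, An=0)
                )
                continue
            ho = float((g[:, 0] != g[:, 1]).mean())
            vals, cnts = _allele_counts(g.ravel())
            p = cnts / cnts.sum()
            he_raw = 1.0 - float((p**2).sum())
            he = (2 * n) / (2 * n - 1) * he_raw if n > 1 else he_raw
            if he > 0:
                fis_nei = 1.0 - ho / he
                fab = wc_components_single_pop(g)
                fis_wc = fab
            else:
                fis_nei = np.nan
                fis_wc = np.nan
            if g_use > n:
                ar = np.nan
            else:
                ar = hurlbert_rarefaction(cnts, 2 * g_use) if g_use > 0 else np.nan
            rows.append(
                dict(locus=locus, population=pop, n=n, Ho=ho, He=he,
                     Fis_wc=fis_wc, Fis_nei=fis_nei, Ar=ar, An=len(vals))
            )
    return pd.DataFrame(rows)


def wc_components_single_pop(g: np.ndarray) -> float:
    """Weir–Cockerham f (F_IS) within a single population at one locus.

    With one population the among-population component vanishes and
    ``f = 1 - sum(c) / sum(b + c)`` over alleles, which reduces to the
    small-sample corrected heterozygote-deficit estimator used by FSTAT.
    """
    a, b, c = _wc_abc(None, [g])
    denom = (b + c).sum()
    return float(1.0 - c.sum() / denom) if denom > 0 else np.nan


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components

def _wc_abc(_unused, pops_geno: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-allele variance components (a, b, c) at one locus.

    ``pops_geno`` is a list of ``(n_i, 2)`` arrays of non-missing genotypes,
    one per population; populations with no data are expected to be dropped
    by the caller.  Returns arrays over the alleles observed in the pooled
    sample.
    """
    pops_geno = [g for g in pops_geno if len(g) > 0]
    r = len(pops_geno)
    n_i = np.array([len(g) for g in pops_geno], dtype=float)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops_geno]))

    nbar = n_i.mean()
    n_total = n_i.sum()
    if r > 1:
        nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    else:
        nc = nbar

    a_out = np.zeros(len(alleles))
    b_out = np.zeros(len(alleles))
    c_out = np.zeros(len(alleles))
    for k, al in enumerate(alleles):
        p_i = np.array([(g == al).mean() for g in pops_geno])
        h_i = np.array([((g == al).sum(axis=1) == 1).mean() for g in pops_geno])
        pbar = (n_i * p_i).sum() / n_total
        hbar = (n_i * h_i).sum() / n_total
        if r > 1:
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        else:
            s2 = 0.0
        if nbar > 1:
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = b = 0.0
        c = hbar / 2.0
        a_out[k], b_out[k], c_out[k] = a, b, c
    return a_out, b_out, c_out


@dataclass
class FstResult:
    """Weir–Cockerham multilocus F-statistics with optional inference.

    ``theta`` (F_ST) is ``sum(a) / sum(a+b+c)`` over all alleles and loci;
    negative values are retained.  ``p_value`` is filled by
    :func:`permutation_fst_test`; ``q_significant`` by :func:`bh_fdr`.
    """

    theta: float
    f_is: float
    f_it: float
    per_locus: pd.DataFrame
    scope: str = "global"
    p_value: float | None = None
    q_significant: bool | None = None


def wc_fstats(gm: GenotypeMatrix, pops: list[str] | None = None) -> FstResult:
    """Multilocus Weir–Cockerham F-statistics over the given populations.

    Raises on a single population; if every locus is monomorphic the result
    carries NaN theta (flagged undefined).
    """
    pops = pops if pops is not None else gm.pop_names
    if len(pops) < 2:
        raise ValueError("F-statistics require at least two populations")
    idx_by_pop = {p: gm.pop_indices(p) for p in pops}

    rows = []
    sum_a = sum_b = sum_c = 0.0
    for j, locus in enumerate(gm.loci):
        pops_geno = []
        for p in pops:
            g = gm.calls[idx_by_pop[p], j, :]
            g = g[(g != 0).all(axis=1)]
            if len(g) > 0:
                pops_geno.append(g)
        if len(pops_geno) < 2:
            rows.append(dict(locus=locus, a=np.nan, b=np.nan, c=np.nan, theta=np.nan))
            continue
        pooled = np.concatenate([g.ravel() for g in pops_geno])
        if len(np.unique(pooled)) < 2:  # monomorphic: no information
            rows.append(dict(locus=locus, a=0.0, b=0.0, c=0.0, theta=np.nan))
            continue
        a, b, c = _wc_abc(None, pops_geno)
        ta, tb, tc = a.sum(), b.sum(), c.sum()
        sum_a += ta
        sum_b += tb
        sum_c += tc
        theta_l = ta / (ta + tb + tc) if (ta + tb + tc) != 0 else np.nan
        rows.append(dict(locus=locus, a=ta, b=tb, c=tc, theta=theta_l))

    denom = sum_a + sum_b + sum_c
    theta = sum_a / denom if denom > 0 else np.nan
    f_is = 1.0 - sum_c / (sum_b + sum_c) if (sum_b + sum_c) > 0 else np.nan
    f_it = 1.0 - sum_c / denom if denom > 0 else np.nan
    scope = "global" if len(pops) > 2 else "pairwise"
    return FstResult(theta=float(theta), f_is=float(f_is), f_it=float(f_it),
                     per_locus=pd.DataFrame(rows), scope=scope)


def pairwise_fst(
    gm: GenotypeMatrix,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Weir–Cockerham theta for every population pair.

    With ``n_perm > 0`` a pair-only genotype permutation p-value is attached
    for each pair.  Returns a long-format frame (pop_i, pop_j, theta, p).
    """
    pops = gm.pop_names
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = [pops[i], pops[j]]
            sub = gm.subset_pops(pair)
            res = wc_fstats(sub, pair)
            p = np.nan
            if n_perm > 0:
                p = permutation_fst_test(
                    sub, n_perm=n_perm, statistic="theta",
                    seed=int(rng.integers(2**31 - 1)),
                )["p_value"]
            rows.append(dict(pop_i=pops[i], pop_j=pops[j], theta=res.theta, p=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation inference

def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood ratio G = 2 * sum O * ln(O / E) on a contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    e = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / e[mask])).sum())


def _multilocus_g(gm: GenotypeMatrix, pops: list[str]) -> float:
    """Allele-count G summed over loci (random-mating assumption: genes are
    the sampling unit)."""
    total = 0.0
    for j in range(gm.n_loci):
        cols = []
        alleles = None
        per_pop = []
        for p in pops:
            g = gm.calls[gm.pop_indices(p), j, :]
            g = g[(g != 0).all(axis=1)].ravel()
            per_pop.append(g)
        pooled = np.concatenate(per_pop) if per_pop else np.array([])
        if pooled.size == 0:
            continue
        alleles = np.unique(pooled)
        if len(alleles) < 2:
            continue
        for g in per_pop:
            cols.append([(g == al).sum() for al in alleles])
        total += g_statistic(np.array(cols))
    return total


def permutation_fst_test(
    gm: GenotypeMatrix,
    n_perm: int = 10_000,
    statistic: str = "theta",
    seed: int | None = None,
    pops: list[str] | None = None,
) -> dict:
    """Test population differentiation by permuting whole multilocus
    genotypes among populations.

    ``statistic`` is ``"theta"`` (Weir–Cockerham) or ``"G"`` (allele-count
    log-likelihood G summed over loci).  One-sided
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    pops = pops if pops is not None else gm.pop_names
    sub = gm.subset_pops(pops)
    rng = np.random.default_rng(seed)

    def stat(m: GenotypeMatrix) -> float:
        if statistic == "theta":
            return wc_fstats(m, m.pop_names).theta
        if statistic == "G":
            return _multilocus_g(m, m.pop_names)
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = stat(sub)
    labels = np.array(sub.populations)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        m = GenotypeMatrix(sub.individual_ids, list(perm), sub.loci, sub.calls)
        if stat(m) >= obs:
            hits += 1
    return {"statistic": statistic, "observed": obs,
            "p_value": (1 + hits) / (n_perm + 1), "n_perm": n_perm}


def hwe_test(
    gm: GenotypeMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hardy–Weinberg tests per population and locus.

    Alleles are permuted within the population at the locus (gametes
    reshuffled into diploids) and the two-sided p-value compares ``|f|`` of
    the Weir–Cockerham F_IS.  Monomorphic cells are reported as NaN.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop in gm.pop_names:
        idx = gm.pop_indices(pop)
        for j, locus in enumerate(gm.loci):
            g = gm.calls[idx, j, :]
            g = g[(g != 0).all(axis=1)]
            if len(g) < 2 or len(np.unique(g.ravel())) < 2:
                rows.append(dict(population=pop, locus=locus, fis=np.nan, p=np.nan))
                continue
            obs = wc_components_single_pop(g)
            genes = g.ravel().copy()
            hits = 0
            for _ in range(n_perm):
                rng.shuffle(genes)
                perm = genes.reshape(-1, 2)
                if abs(wc_components_single_pop(perm)) >= abs(obs):
                    hits += 1
            rows.append(dict(population=pop, locus=locus, fis=obs,
                             p=(1 + hits) / (n_perm + 1)))
    return pd.DataFrame(rows)


def _two_locus_g(ga: np.ndarray, gb: np.ndarray) -> float:
    """G on the contingency table of unordered single-locus genotypes."""
    def keys(g: np.ndarray) -> np.ndarray:
        lo = np.minimum(g[:, 0], g[:, 1])
        hi = np.maximum(g[:, 0], g[:, 1])
        return lo * 100_000 + hi

    ka, kb = keys(ga), keys(gb)
    ua, ub = np.unique(ka), np.unique(kb)
    table = np.zeros((len(ua), len(ub)))
    ia = np.searchsorted(ua, ka)
    ib = np.searchsorted(ub, kb)
    np.add.at(table, (ia, ib), 1)
    return g_statistic(table)


def ld_test(
    gm: GenotypeMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Genotypic disequilibrium between every locus pair within each
    population.

    One locus's genotypes are permuted among individuals (breaking any
    association while preserving single-locus genotype frequencies); the
    statistic is the two-locus genotype-table G.  Pairs where either locus
    is monomorphic are skipped (NaN).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop in gm.pop_names:
        idx = gm.pop_indices(pop)
        for j1 in range(gm.n_loci):
            for j2 in range(j1 + 1, gm.n_loci):
                g1 = gm.calls[idx, j1, :]
                g2 = gm.calls[idx, j2, :]
                keep = (g1 != 0).all(axis=1) & (g2 != 0).all(axis=1)
                g1, g2 = g1[keep], g2[keep]
                if (
                    len(g1) < 2
                    or len(np.unique(g1.ravel())) < 2
                    or len(np.unique(g2.ravel())) < 2
                ):
                    rows.append(dict(population=pop, locus1=gm.loci[j1],
                                     locus2=gm.loci[j2], g=np.nan, p=np.nan))
                    continue
                obs = _two_locus_g(g1, g2)
                hits = 0
                order = np.arange(len(g2))
                for _ in range(n_perm):
                    rng.shuffle(order)
                    if _two_locus_g(g1, g2[order]) >= obs:
                        hits += 1
                rows.append(dict(population=pop, locus1=gm.loci[j1],
                                 locus2=gm.loci[j2], g=obs,
                                 p=(1 + hits) / (n_perm + 1)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at FDR level ``q``.

    NaN entries are never rejected and do not count toward the family size.
    Apply separately per test family (pairwise F_ST together, HWE together,
    disequilibrium together).
    """
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if not ok.any():
        return out
    if (p[ok] <= 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    adj = false_discovery_control(p[ok], method="bh")
    out[ok] = adj <= q
    return out
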