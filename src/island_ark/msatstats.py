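"""Microsatellite summary statistics.

Unbiased expected heterozygosity, rarefaction allelic richness, Monte-Carlo
/ exact Hardy-Weinberg tests with sequential Holm correction, and
Weir-Cockerham (1984) F_ST with a permutation test.  Missing genotypes are
excluded locus-wise (an individual missing one locus still contributes to
the others).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable

log = logging.getLogger(__name__)

UNDEFINED = float("nan")


@dataclass
class LocusPopSummary:
    """Per-locus, per-population allele summary."""
    n_copies: int
    allele_freqs: dict[int, float]
    H_exp: float
    A_R: float


@dataclass
class FstMatrix:
    """Pairwise and overall Weir-Cockerham theta."""
    labels: list[str]
    values: np.ndarray
    overall: float
    p_overall: float = UNDEFINED


def _copies(table: GenotypeTable, pop: str, locus: str) -> np.ndarray:
    """Non-missing gene copies of one locus in one population."""
    li = table.loci.index(locus)
    mask = table.pop_mask(pop)
    pairs = table.alleles[mask, li, :]
    flat = pairs.reshape(-1)
    return flat[flat != MISSING]


def expected_heterozygosity(table: GenotypeTable, pop: str, locus: str) -> float:
    """Nei's unbiased expected heterozygosity n/(n-1)(1 - sum p^2).

    ``n`` counts gene copies; fewer than 2 copies returns ``nan``.
    """
    copies = _copies(table, pop, locus)
    n = len(copies)
    if n < 2:
        return UNDEFINED
    _, counts = np.unique(copies, return_counts=True)
    p = counts / n
    return n / (n - 1) * (1.0 - float((p ** 2).sum()))


def allelic_richness(table: GenotypeTable, pop: str, locus: str, g: int) -> float:
    """Rarefied allelic richness: expected distinct alleles in ``g`` copies.

    A_R = sum_a [1 - C(N - N_a, g) / C(N, g)] over observed alleles.
    """
    copies = _copies(table, pop, locus)
    N = len(copies)
    if g < 1 or g > N:
        raise ValueError(f"rarefaction size g={g} outside [1, {N}]")
    _, counts = np.unique(copies, return_counts=True)
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - Na, g) / denom if N - Na >= g else 1.0
                     for Na in counts))


def rarefaction_base(table: GenotypeTable, locus: str,
                     pops: list[str] | None = None) -> int:
    """Smallest non-missing gene-copy count over populations, per locus."""
    pops = pops or table.populations
    return min(len(_copies(table, p, locus)) for p in pops)


def locus_pop_summary(table: GenotypeTable, pop: str, locus: str,
                      g: int | None = None) -> LocusPopSummary:
    copies = _copies(table, pop, locus)
    n = len(copies)
    vals, counts = np.unique(copies, return_counts=True)
    freqs = {int(v): float(c) / n for v, c in zip(vals, counts)} if n else {}
    h = expected_heterozygosity(table, pop, locus)
    gg = g if g is not None else rarefaction_base(table, locus)
    ar = allelic_richness(table, pop, locus, min(gg, n)) if n else UNDEFINED
    return LocusPopSummary(n_copies=n, allele_freqs=freqs, H_exp=h, A_R=ar)


def summarize_table(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Per-population mean (SD) of A_R and H over loci — a Table-1 layout."""
    rows = []
    for pop in table.populations:
        n_ind = int(table.pop_mask(pop).sum())
        ars, hs = [], []
        for locus in table.loci:
            s = locus_pop_summary(table, pop, locus, g=g)
            if not math.isnan(s.A_R):
                ars.append(s.A_R)
            if not math.isnan(s.H_exp):
                hs.append(s.H_exp)
        rows.append({
            "population": pop, "n": n_ind,
            "A_R_mean": float(np.mean(ars)), "A_R_sd": float(np.std(ars, ddof=1)),
            "H_mean": float(np.mean(hs)), "H_sd": float(np.std(hs, ddof=1)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _log_cond_prob(geno_counts: dict[tuple[int, int], int],
                   allele_counts: dict[int, int], n_ind: int) -> float:
    """Levene's conditional log-probability of a genotype table given alleles."""
    het = sum(c for (a, b), c in geno_counts.items() if a != b)
    lp = math.lgamma(n_ind + 1) + het * math.log(2.0)
    lp += sum(math.lgamma(c + 1) for c in allele_counts.values())
    lp -= math.lgamma(2 * n_ind + 1)
    lp -= sum(math.lgamma(c + 1) for c in geno_counts.values())
    return lp


def _enumerate_tables(alleles: list[int], counts: list[int], limit: int = 200_000):
    """All genotype tables consistent with the allele counts (small cases)."""
    pairs = list(combinations_with_replacement(range(len(alleles)), 2))
    out: list[dict[tuple[int, int], int]] = []

    def rec(idx: int, remaining: list[int], acc: dict):
        if len(out) > limit:
            raise OverflowError
        if idx == len(pairs):
            if all(r == 0 for r in remaining):
                out.append(dict(acc))
            return
        i, j = pairs[idx]
        if i == j:
            mx = remaining[i] // 2
        else:
            mx = min(remaining[i], remaining[j])
        for c in range(mx + 1):
            remaining[i] -= 2 * c if i == j else c
            if i != j:
                remaining[j] -= c
            if c:
                acc[(alleles[i], alleles[j])] = c
            rec(idx + 1, remaining, acc)
            acc.pop((alleles[i], alleles[j]), None)
            remaining[i] += 2 * c if i == j else c
            if i != j:
                remaining[j] += c

    rec(0, list(counts), {})
    return out


def hwe_exact_test(table: GenotypeTable, pop: str, locus: str,
                   n_steps: int = 100_000, seed: int | None = None) -> float:
    """Exact / Monte-Carlo Hardy-Weinberg test for one locus in one population.

    p = probability mass (exact) or fraction (Monte Carlo over random
    pairings of the observed allele pool) of genotype tables whose Levene
    conditional probability is <= the observed table's.  Monomorphic loci
    return 1 by convention; exact enumeration is auto-selected when the
    table space is small.
    """
    li = table.loci.index(locus)
    mask = table.pop_mask(pop)
    pairs = table.alleles[mask, li, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    n_ind = len(pairs)
    if n_ind < 3:
        raise ValueError("need >= 3 genotyped individuals")
    flat = pairs.reshape(-1)
    vals, counts = np.unique(flat, return_counts=True)
    if len(vals) < 2:
        return 1.0
    allele_counts = {int(v): int(c) for v, c in zip(vals, counts)}
    obs_counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        key = (int(min(a, b)), int(max(a, b)))
        obs_counts[key] = obs_counts.get(key, 0) + 1
    lp_obs = _log_cond_prob(obs_counts, allele_counts, n_ind)

    try:
        tables = _enumerate_tables(list(map(int, vals)), list(map(int, counts)))
        total, mass = 0.0, 0.0
        for t in tables:
            lp = _log_cond_prob(t, allele_counts, n_ind)
            p = math.exp(lp)
            total += p
            if lp <= lp_obs + 1e-12:
                mass += p
        return mass / total
    except OverflowError:
        pass

    if seed is None:
        raise ValueError("seed is mandatory for the Monte-Carlo test")
    rng = np.random.default_rng(seed)
    pool = flat.copy()
    hits = 0
    for _ in range(n_steps):
        rng.shuffle(pool)
        sim = pool.reshape(-1, 2)
        sim_counts: dict[tuple[int, int], int] = {}
        for a, b in sim:
            key = (int(min(a, b)), int(max(a, b)))
            sim_counts[key] = sim_counts.get(key, 0) + 1
        if _log_cond_prob(sim_counts, allele_counts, n_ind) <= lp_obs + 1e-12:
            hits += 1
    return hits / n_steps


def holm_correction(pvals: list[float], alpha: float = 0.05) -> list[bool]:
    """Sequential Bonferroni-Holm step-down decisions, in input order.

    Sorted p_(i) is compared against alpha/(m-i+1); rejection stops at the
    first failure.
    """
    if not pvals:
        raise ValueError("pvals must be non-empty")
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    order = np.argsort(pvals)
    reject = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(table: GenotypeTable, pops: list[str]
                   ) -> tuple[float, float]:
    """Sums of the WC (1984) a and a+b+c variance components over loci/alleles."""
    num = den = 0.0
    masks = [table.pop_mask(p) for p in pops]
    for li in range(len(table.loci)):
        per_pop = []
        for mask in masks:
            pairs = table.alleles[mask, li, :]
            pairs = pairs[pairs[:, 0] != MISSING]
            if len(pairs) == 0:
                per_pop = []
                break
            per_pop.append(pairs)
        if not per_pop:
            log.warning("locus %s dropped: all-missing in one population",
                        table.loci[li])
            continue
        r = len(per_pop)
        n_i = np.array([len(p) for p in per_pop], dtype=float)
        if (n_i < 2).any() or r < 2:
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        alleles = np.unique(np.concatenate([p.reshape(-1) for p in per_pop]))
        for al in alleles:
            p_i = np.array([(pp == al).sum() / (2 * len(pp)) for pp in per_pop])
            h_i = np.array([((pp[:, 0] == al) != (pp[:, 1] == al)).mean()
                            for pp in per_pop])
            pbar = float((n_i * p_i).sum() / (r * nbar))
            s2 = float((n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((n_i * h_i).sum() / (r * nbar))
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num, den


def _theta(table: GenotypeTable, pops: list[str]) -> float:
    num, den = _wc_components(table, pops)
    return num / den if den != 0 else UNDEFINED


def fst(table: GenotypeTable, permutations: int = 0,
        seed: int | None = None) -> FstMatrix:
    """Pairwise and overall multi-locus Weir-Cockerham theta.

    The multi-locus estimate is the ratio of summed variance components
    (never a mean of ratios).  With ``permutations`` > 0, individuals are
    permuted across populations for an overall p-value
    (fraction of permuted thetas >= observed).
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = _theta(table, [pops[i], pops[j]])
    overall = _theta(table, pops)
    p_overall = UNDEFINED
    if permutations > 0:
        if seed is None:
            raise ValueError("seed is mandatory for the permutation test")
        rng = np.random.default_rng(seed)
        labels = [table.pops[i] for i in table.individuals]
        hits = 0
        for _ in range(permutations):
            perm = list(labels)
            rng.shuffle(perm)
            shuffled = GenotypeTable(
                list(table.individuals),
                dict(zip(table.individuals, perm)),
                list(table.loci), table.alleles.copy())
            if _theta(shuffled, shuffled.populations) >= overall - 1e-12:
                hits += 1
        p_overall = hits / permutations
    return FstMatrix(labels=pops, values=values, overall=overall,
                     p_overall=p_overall)
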