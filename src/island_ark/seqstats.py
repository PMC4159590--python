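"""Sequence diversity, neutrality tests and mismatch-distribution dating.

Implements the mtDNA side of the analysis: haplotype and nucleotide
diversity (with Nei's standard variances), Tajima's D, Fu's Fs, Ramos-Onsins
& Rozas's R2, the mismatch distribution with the Rogers-Harpending
sudden-expansion model fit (tau, theta0, theta1 minimising SSD), a
parametric-bootstrap SSD p-value, and the conversion of tau to an expansion
time in years through a mutation-rate/generation-time clock.

Statistics that are undefined for an input (e.g. Tajima's D with no
segregating sites) return ``nan`` — an explicit marker, never a silent zero.
Fu's Fs can degenerate to ``+/-inf`` when the tail probability underflows;
this is returned as the signed infinity with a warning.

Site handling follows complete deletion by default: any column containing a
gap or ``N`` in an analysed sequence is dropped before anything is counted,
and the per-site scaling of pi uses the analysed-site count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .io_formats import SequenceAlignment

log = logging.getLogger(__name__)

UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return math.isnan(x)


@dataclass
class DiversityStats:
    """Summary diversity of one alignment (Table-3 style row)."""
    n: int
    S: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    k: float                      # mean pairwise differences per sequence
    sites: int                    # analysed sites after deletion policy


@dataclass
class MismatchFit:
    """Sudden-expansion model fitted to a mismatch distribution."""
    tau: float
    theta0: float
    theta1: float
    ssd: float
    observed: np.ndarray
    p_ssd: float = UNDEFINED
    converged: bool = True


@dataclass
class ClockConstants:
    """Molecular-clock constants used to convert tau into years."""
    mu_site: float                # mutations / site / year
    L: int                        # sites the rate applies to
    gen_time: float = 1.0         # years per generation

    def __post_init__(self) -> None:
        if self.mu_site <= 0 or self.L <= 0 or self.gen_time <= 0:
            raise ValueError("clock constants must be strictly positive")


# ---------------------------------------------------------------------------
# site handling
# ---------------------------------------------------------------------------

def analyzed_matrix(aln: SequenceAlignment, policy: str = "complete") -> np.ndarray:
    """Character matrix restricted to analysed columns.

    ``complete`` drops every column containing '-' or 'N' in any sequence
    (the default of the software this mirrors); ``pairwise`` keeps all
    columns and leaves ambiguity to the pairwise counters.
    """
    if policy == "complete":
        bad = ((aln.seqs == "-") | (aln.seqs == "N")).any(axis=0)
        return aln.seqs[:, ~bad]
    if policy == "pairwise":
        return aln.seqs
    raise ValueError(f"unknown site policy {policy!r}")


def _pairwise_diffs(mat: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise difference counts (n*(n-1)/2 entries)."""
    n = mat.shape[0]
    codes = np.searchsorted(np.array(["-", "A", "C", "G", "N", "T"]), mat)
    out = np.empty(n * (n - 1) // 2, dtype=np.int64)
    idx = 0
    for i in range(n - 1):
        d = (codes[i + 1:] != codes[i]).sum(axis=1)
        out[idx:idx + len(d)] = d
        idx += len(d)
    return out


def segregating_sites(aln: SequenceAlignment, policy: str = "complete") -> int:
    """Number of analysed columns carrying two or more distinct bases."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = analyzed_matrix(aln, policy)
    return int(sum((col != col[0]).any() for col in mat.T))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def diversity(aln: SequenceAlignment, policy: str = "complete") -> DiversityStats:
    """Haplotype and nucleotide diversity with Nei's standard variances.

    h = n/(n-1) (1 - sum f_i^2) over haplotype frequencies; pi = mean
    pairwise differences per analysed site.  The h variance is Nei (1987)
    eq. 8.12 and the pi variance the total (stochastic + sampling) variance
    of Nei's eq. 10.7.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = analyzed_matrix(aln, policy)
    n, sites = aln.n, mat.shape[1]
    haplos = ["".join(r) for r in mat]
    _, counts = np.unique(haplos, return_counts=True)
    f = counts / n
    sum2, sum3 = float((f ** 2).sum()), float((f ** 3).sum())
    h = n / (n - 1) * (1.0 - sum2)
    var_h = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    diffs = _pairwise_diffs(mat)
    k = float(diffs.mean())
    pi = k / sites if sites else 0.0
    var_pi = ((n + 1) / (3.0 * (n - 1)) * pi / sites
              + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) * pi * pi) \
        if sites else 0.0
    S = int(sum((col != col[0]).any() for col in mat.T))
    return DiversityStats(n=n, S=S, h=h, h_sd=math.sqrt(max(var_h, 0.0)),
                          pi=pi, pi_sd=math.sqrt(max(var_pi, 0.0)),
                          k=k, sites=sites)


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1 ** 2 + a2)}


def tajimas_d(aln: SequenceAlignment, policy: str = "complete") -> float:
    """Tajima's (1989) D; ``nan`` when S = 0."""
    if aln.n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    mat = analyzed_matrix(aln, policy)
    S = int(sum((col != col[0]).any() for col in mat.T))
    if S == 0:
        return UNDEFINED
    k = float(_pairwise_diffs(mat).mean())
    c = _tajima_constants(aln.n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k - S / c["a1"]) / denom


def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the triangular recurrence, in log space."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0                                  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        cur[1:m + 1] = np.logaddexp(
            prev[0:m] ,
            prev[1:m + 1] + math.log(m - 1) if m > 1 else -np.inf)
        if m == 1:
            cur[1] = 0.0
        prev = cur
    return prev


_STIRLING_CACHE: dict[int, np.ndarray] = {}


def _ewens_log_probs(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling formula."""
    if n not in _STIRLING_CACHE:
        _STIRLING_CACHE[n] = _log_stirling_first(n)
    ls = _STIRLING_CACHE[n]
    k = np.arange(1, n + 1)
    log_rising = float(gammaln(theta + n) - gammaln(theta))
    return ls[1:] + k * math.log(theta) - log_rising


def fus_fs(aln: SequenceAlignment, policy: str = "complete") -> float:
    """Fu's (1997) Fs = ln(S'/(1-S')), S' = P(K >= k_obs | theta = k-hat).

    The Ewens sampling-formula tail uses exact log-space Stirling numbers of
    the first kind; theta is estimated by the mean pairwise difference.
    Returns ``nan`` for a single haplotype and signed infinity when the tail
    probability underflows to 0 or 1.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = analyzed_matrix(aln, policy)
    haplos = ["".join(r) for r in mat]
    k_obs = len(set(haplos))
    if k_obs < 2:
        return UNDEFINED
    theta = float(_pairwise_diffs(mat).mean())
    if theta <= 0:
        return UNDEFINED
    logp = _ewens_log_probs(aln.n, theta)
    from scipy.special import logsumexp
    log_tail = float(logsumexp(logp[k_obs - 1:]))
    log_head = float(logsumexp(logp[:k_obs - 1])) if k_obs > 1 else -np.inf
    if log_tail == -np.inf or log_head == -np.inf:
        sign = 1.0 if log_tail > log_head else -1.0
        log.warning("Fu's Fs tail probability underflowed; returning %sinf",
                    "+" if sign > 0 else "-")
        return sign * math.inf
    return log_tail - log_head       # ln(S'/(1-S')) with 1-S' = head


def rozas_r2(aln: SequenceAlignment, policy: str = "complete") -> float:
    """Ramos-Onsins & Rozas's (2002) R2; ``nan`` when S = 0.

    R2 = sqrt(mean_i (U_i - k/2)^2) / S, with U_i the number of singleton
    mutations carried by sequence i.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = analyzed_matrix(aln, policy)
    n = aln.n
    S = int(sum((col != col[0]).any() for col in mat.T))
    if S == 0:
        return UNDEFINED
    U = np.zeros(n)
    for col in mat.T:
        vals, counts = np.unique(col, return_counts=True)
        for v, c in zip(vals, counts):
            if c == 1:
                U[col == v] += 1
    k = float(_pairwise_diffs(mat).mean())
    return math.sqrt(float(((U - k / 2.0) ** 2).mean())) / S


# ---------------------------------------------------------------------------
# mismatch distribution and sudden-expansion fit
# ---------------------------------------------------------------------------

def mismatch_distribution(aln: SequenceAlignment,
                          policy: str = "complete") -> np.ndarray:
    """Normalised histogram of pairwise difference counts, classes 0..max."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    diffs = _pairwise_diffs(analyzed_matrix(aln, policy))
    hist = np.bincount(diffs)
    return hist / hist.sum()


def expected_mismatch(tau: float, theta0: float, theta1: float,
                      n_classes: int) -> np.ndarray:
    """Rogers-Harpending expected mismatch probabilities for classes 0..n-1.

    F_j = F^(θ1)_j + exp(-tau (θ1+1)/θ1) * sum_{i<=j} tau^i/i! *
          (F^(θ0)_{j-i} - F^(θ1)_{j-i}),   F^(θ)_j = θ^j / (1+θ)^{j+1}.
    """
    j = np.arange(n_classes)
    theta0 = max(theta0, 0.0)
    theta1 = max(theta1, 1e-12)

    def geo(th: float) -> np.ndarray:
        if th <= 0:
            out = np.zeros(n_classes)
            out[0] = 1.0
            return out
        return np.exp(j * math.log(th) - (j + 1) * math.log1p(th))

    f0, f1 = geo(theta0), geo(theta1)
    if tau <= 0:
        return f0
    # Poisson(tau) convolution of the equilibrium difference
    logpois = j * math.log(tau) - gammaln(j + 1)
    pois = np.exp(logpois - tau)
    conv = np.convolve(pois, f0 - f1)[:n_classes]
    decay = math.exp(-tau / theta1) if tau / theta1 < 700 else 0.0
    return f1 + decay * conv


def fit_sudden_expansion(observed: np.ndarray, n: int,
                         n_restarts: int = 10) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch.

    Nelder-Mead inside bounds tau in [0,50], theta0 in [0,20], theta1 in
    [theta0, 5000], restarted from quantile-spaced initial points; the best
    SSD over restarts is kept.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size == 0 or abs(obs.sum() - 1.0) > 1e-6:
        raise ValueError("observed must be a normalised mismatch vector")
    nc = obs.size
    mean_k = float((np.arange(nc) * obs).sum())

    LO = np.array([0.0, 0.0, 1e-6])
    HI = np.array([50.0, 20.0, 5000.0])

    def ssd_of(p: np.ndarray) -> float:
        tau, th0, th1 = np.clip(p, LO, HI)
        th1 = max(th1, th0)
        model = expected_mismatch(tau, th0, th1, nc)
        return float(((obs - model) ** 2).sum())

    q = np.linspace(0.15, 0.85, n_restarts)
    best, best_ssd = None, math.inf
    converged = False
    for qi in q:
        x0 = np.array([max(mean_k, 0.1) * 2 * qi,
                       max(mean_k, 0.1) * qi,
                       10.0 + 4990.0 * qi])
        res = minimize(ssd_of, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        if res.fun < best_ssd:
            best_ssd, best = float(res.fun), np.clip(res.x, LO, HI)
            converged = bool(res.success)
    if best is None:
        raise RuntimeError("mismatch fit failed from every start")
    tau, th0, th1 = best
    th1 = max(th1, th0)
    return MismatchFit(tau=float(tau), theta0=float(th0), theta1=float(th1),
                       ssd=best_ssd, observed=obs, converged=converged)


def _simulate_scaled_mismatch(n: int, tau: float, theta0: float, theta1: float,
                              rng: np.random.Generator) -> np.ndarray:
    """One coalescent sample under the fitted expansion, in tau (= 2ut) units.

    Pairwise coalescence rate is 1/theta(t) per tau unit (theta1 at present,
    theta0 past the expansion at time tau); mutations per lineage are
    Poisson(branch/2).
    """
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    active = list(range(n))
    t, nxt = 0.0, n
    while len(active) > 1:
        kk = len(active)
        theta = theta1 if t < tau else theta0
        rate = kk * (kk - 1) / 2.0 / max(theta, 1e-12)
        wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if t < tau < t + wait and theta0 != theta1:
            t = tau                          # epoch boundary, redraw
            continue
        t += wait
        i, jx = rng.choice(kk, size=2, replace=False)
        a, b = active[i], active[jx]
        times[nxt] = t
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    # mutations: Poisson(branch/2) per branch; then pairwise differences
    muts = np.zeros(2 * n - 1)
    for v in range(2 * n - 2):
        branch = times[parent[v]] - times[v]
        muts[v] = rng.poisson(branch / 2.0)
    # accumulate root-to-tip mutation counts, then pair differences via
    # shared-ancestor subtraction is wrong for counts; instead sum mutations
    # on the path between tips: depth(a)+depth(b)-2*depth(mrca) in mutation
    # units requires per-branch values, so compute tip paths explicitly.
    depth = np.zeros(2 * n - 1)
    order = np.argsort(times)[::-1]          # root first
    for v in order:
        if parent[v] >= 0:
            depth[v] = depth[parent[v]] + muts[v]
    # mrca mutation depth: walk up; n is small in bootstrap use
    anc: list[set[int]] = []
    for tip in range(n):
        s, v = set(), tip
        while v != -1:
            s.add(v)
            v = parent[v]
        anc.append(s)
    diffs = []
    for i in range(n - 1):
        for jx in range(i + 1, n):
            common = anc[i] & anc[jx]
            m = min(common, key=lambda v: times[v])
            diffs.append(depth[i] + depth[jx] - 2 * depth[m])
    hist = np.bincount(np.asarray(diffs, dtype=np.int64))
    return hist / hist.sum()


def ssd_pvalue(fit: MismatchFit, n: int, n_boot: int = 1000,
               seed: int | None = None, n_restarts: int = 3) -> float:
    """Parametric-bootstrap p-value for the sudden-expansion SSD.

    Simulates ``n_boot`` coalescent samples of size ``n`` under the fitted
    (tau, theta0, theta1), refits each, and reports the fraction with
    SSD >= the observed SSD.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        sim = _simulate_scaled_mismatch(n, fit.tau, fit.theta0, fit.theta1, rng)
        refit = fit_sudden_expansion(sim, n, n_restarts=n_restarts)
        if refit.ssd >= fit.ssd - 1e-12:
            count += 1
    return count / n_boot


def expansion_time(tau: float, clock: ClockConstants) -> float:
    """Years before present at which the fitted expansion began.

    tau = 2 u t with u the per-sequence per-generation mutation rate
    (mu_site * L * gen_time), so t = tau / (2 mu_site L) * gen_time years.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau / (2.0 * clock.mu_site * clock.L) * clock.gen_time
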