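"""Approximate Bayesian computation for the colonization model.

Plain rejection ABC: draw the 11 demographic parameters from priors,
simulate microsatellite datasets under the coalescent, reduce each to a
fixed summary vector (per-population expected heterozygosity, allele count
and allele-size variance, plus source-island F_ST and Goldstein's (delta
mu)^2), and retain the draws closest to the observed vector under a
Euclidean distance standardized by the median absolute deviation (MAD) of
the simulated summaries.  Point estimates are posterior modes from a
Gaussian KDE with Silverman bandwidth.

The candidate-source ranking statistic Delta_C is the mean standardized
distance between the observed summaries (candidate population against each
colonized target population) and ``n_sim`` model simulations using the
candidate as source; the smallest Delta_C marks the most likely source.

Priors here are this package's reconstruction (documented defaults,
fully overridable); the island-bottleneck onset ``T_ob`` is drawn as a
fraction of its admissible window so every draw is a valid model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalsim import DemographicModel, SimSpec, simulate_dataset
from .io_formats import MISSING, GenotypeTable

log = logging.getLogger(__name__)

PARAMS = DemographicModel.param_names()


@dataclass
class PriorSpec:
    """Per-parameter prior families and bounds.

    ``dists`` maps each of the 11 model parameters to
    ``(family, low, high)`` with family in {"uniform", "loguniform"}.
    ``T_ob`` is special-cased as a fraction in [0, 1] of the admissible
    bottleneck window ``[0, T_col - d_f - d_ob]``.
    """
    dists: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        missing = set(PARAMS) - set(self.dists)
        extra = set(self.dists) - set(PARAMS)
        if missing or extra:
            raise ValueError(f"priors must cover the model parameters "
                             f"exactly once (missing {sorted(missing)}, "
                             f"extra {sorted(extra)})")
        for name, (fam, lo, hi) in self.dists.items():
            if fam not in ("uniform", "loguniform"):
                raise ValueError(f"{name}: unknown family {fam!r}")
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: bounds must be finite with lo < hi")
            if fam == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs lo > 0")


def default_priors() -> PriorSpec:
    """Reconstruction of plausible colonization priors (overridable).

    Current sizes span the effective-size range of abundant small rodents
    (10^3 - 10^6); bottleneck sizes are log-uniform over 10 - 10^3 founders
    and bottleneck durations are short (1 - 30 generations), consistent with
    a founding event followed by instantaneous growth.  Under longer or more
    extreme bottlenecks the prior-predictive source-island divergence sits
    above any realistically related pair and the mean-distance source
    ranking degenerates, so the reconstruction keeps the predictive mass in
    the mild-drift regime the original source-ranking behaviour implies.
    """
    return PriorSpec({
        "N_c": ("loguniform", 1e3, 1e6),
        "N_o": ("loguniform", 1e3, 1e6),
        "T_col": ("uniform", 100, 1e4),
        "N_f": ("loguniform", 10, 1e3),
        "d_f": ("uniform", 1, 30),
        "T_ob": ("uniform", 0, 1),          # fraction of admissible window
        "N_ob": ("loguniform", 10, 1e3),
        "d_ob": ("uniform", 1, 30),
        "T_cb": ("uniform", 0, 1e4),
        "N_cb": ("loguniform", 10, 1e3),
        "d_cb": ("uniform", 1, 30),
    })


def sample_priors(priors: PriorSpec, M: int,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """``M`` independent prior draws, one column per model parameter."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = {}
    for name in PARAMS:
        fam, lo, hi = priors.dists[name]
        if fam == "uniform":
            cols[name] = rng.uniform(lo, hi, size=M)
        else:
            cols[name] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=M))
    return pd.DataFrame(cols)


def draw_to_model(row) -> DemographicModel:
    """One prior draw mapped to a valid demographic model.

    The founder duration is clipped to the colonization time and the island
    bottleneck is placed inside its admissible window via the ``T_ob``
    fraction.
    """
    p = {k: float(row[k]) for k in PARAMS}
    p["d_f"] = min(p["d_f"], p["T_col"])
    window = max(p["T_col"] - p["d_f"] - p["d_ob"], 0.0)
    if window <= 0:
        p["d_ob"] = 0.0
        p["T_ob"] = 0.0
    else:
        p["T_ob"] = p["T_ob"] * window
    m = DemographicModel(**p)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _pop_arrays(table: GenotypeTable, pops: list[str]) -> dict[str, np.ndarray]:
    return {p: table.alleles[table.pop_mask(p)] for p in pops}


def _per_pop_stats(pairs: np.ndarray) -> tuple[float, float, float]:
    """(mean H, mean allele count, mean allele-size variance) over loci."""
    hs, cnts, vars_ = [], [], []
    for li in range(pairs.shape[1]):
        flat = pairs[:, li, :].reshape(-1)
        flat = flat[flat != MISSING]
        n = len(flat)
        if n < 2:
            continue
        _, counts = np.unique(flat, return_counts=True)
        p = counts / n
        hs.append(n / (n - 1) * (1.0 - float((p ** 2).sum())))
        cnts.append(len(counts))
        vars_.append(float(flat.var(ddof=1)))
    return float(np.mean(hs)), float(np.mean(cnts)), float(np.mean(vars_))


def _pair_fst(a: np.ndarray, b: np.ndarray) -> float:
    """Two-population multi-locus Weir-Cockerham theta on raw allele arrays."""
    num = den = 0.0
    for li in range(a.shape[1]):
        pa = a[:, li, :]
        pb = b[:, li, :]
        pa = pa[pa[:, 0] != MISSING]
        pb = pb[pb[:, 0] != MISSING]
        if len(pa) < 2 or len(pb) < 2:
            continue
        n_i = np.array([len(pa), len(pb)], dtype=float)
        r = 2
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        alleles = np.unique(np.concatenate([pa.reshape(-1), pb.reshape(-1)]))
        p_mat = np.empty((2, len(alleles)))
        h_mat = np.empty((2, len(alleles)))
        for row, pairs in enumerate((pa, pb)):
            eq0 = pairs[:, 0:1] == alleles[None, :]
            eq1 = pairs[:, 1:2] == alleles[None, :]
            p_mat[row] = (eq0.sum(axis=0) + eq1.sum(axis=0)) / (2 * len(pairs))
            h_mat[row] = (eq0 != eq1).mean(axis=0)
        pbar = (n_i[:, None] * p_mat).sum(axis=0) / (r * nbar)
        s2 = (n_i[:, None] * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_mat).sum(axis=0) / (r * nbar)
        a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - hbar / 4) / (nbar - 1))
        b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c_c = hbar / 2
        num += float(a_c.sum())
        den += float((a_c + b_c + c_c).sum())
    return num / den if den != 0 else 0.0


def _dmu2(a: np.ndarray, b: np.ndarray) -> float:
    """Goldstein's (delta mu)^2: squared mean-size difference, mean over loci."""
    vals = []
    for li in range(a.shape[1]):
        fa = a[:, li, :].reshape(-1)
        fb = b[:, li, :].reshape(-1)
        fa = fa[fa != MISSING]
        fb = fb[fb != MISSING]
        if len(fa) and len(fb):
            vals.append((fa.mean() - fb.mean()) ** 2)
    return float(np.mean(vals))


@dataclass
class SummaryVector:
    """Ordered, named summary statistics for one source/targets layout."""
    names: list[str]
    values: np.ndarray


def compute_summaries(table: GenotypeTable, source_pop: str,
                      target_pops: list[str]) -> SummaryVector:
    """Deterministic summary vector for ABC distances.

    Per population (source first): mean H, mean allele count, mean
    allele-size variance over loci; then per target: source-target WC F_ST
    and (delta mu)^2.
    """
    pops = [source_pop] + list(target_pops)
    arrays = _pop_arrays(table, pops)
    names, values = [], []
    for p in pops:
        h, a, v = _per_pop_stats(arrays[p])
        names += [f"H_{p}", f"A_{p}", f"V_{p}"]
        values += [h, a, v]
    for t in target_pops:
        names += [f"FST_{source_pop}_{t}", f"dmu2_{source_pop}_{t}"]
        values += [_pair_fst(arrays[source_pop], arrays[t]),
                   _dmu2(arrays[source_pop], arrays[t])]
    return SummaryVector(names=names, values=np.array(values, dtype=float))


# ---------------------------------------------------------------------------
# rejection and point estimates
# ---------------------------------------------------------------------------

def abc_reject(observed: np.ndarray, simulated: np.ndarray,
               tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    """MAD-standardized Euclidean rejection.

    Returns ``(retained_indices, distances)`` with
    ``len(retained) = ceil(tolerance * M)``.  Statistics whose simulated MAD
    is zero are dropped from the distance with a warning.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    sims = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sims.ndim != 2 or sims.shape[1] != obs.shape[0] or sims.shape[0] < 1:
        raise ValueError("need a (M, d) simulation matrix matching observed")
    mad = np.median(np.abs(sims - np.median(sims, axis=0)), axis=0)
    keep = mad > 0
    if not keep.all():
        log.warning("%d summary statistic(s) with zero MAD dropped",
                    int((~keep).sum()))
    if not keep.any():
        raise ValueError("every summary statistic has zero MAD")
    z = (sims[:, keep] - obs[keep]) / mad[keep]
    distances = np.sqrt((z ** 2).sum(axis=1))
    n_keep = math.ceil(tolerance * sims.shape[0])
    retained = np.argsort(distances, kind="stable")[:n_keep]
    return retained, distances


def posterior_mode(values: np.ndarray) -> float:
    """KDE mode (Gaussian kernel, Silverman bandwidth, 512-point grid).

    Falls back to the median (with a warning) below 20 draws or for a
    degenerate sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 20 or np.ptp(v) == 0:
        if v.size < 20:
            log.warning("posterior_mode: %d < 20 draws, using median", v.size)
        return float(np.median(v))
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class ABCResult:
    """Everything a rejection-ABC fit produces."""
    draws: pd.DataFrame
    summaries: np.ndarray
    summary_names: list[str]
    distances: np.ndarray
    retained: np.ndarray
    modes: dict[str, float]
    tolerance: float
    seed: int

    @property
    def posterior(self) -> pd.DataFrame:
        return self.draws.iloc[self.retained]

    def credible_interval(self, param: str, level: float = 0.95
                          ) -> tuple[float, float]:
        v = self.posterior[param].to_numpy()
        lo = float(np.quantile(v, (1 - level) / 2))
        hi = float(np.quantile(v, 1 - (1 - level) / 2))
        return lo, hi


def simulate_reference(priors: PriorSpec, n_target: int, n_source: int,
                       n_loci: int, M: int, seed: int,
                       mu_msat: float = 2e-4
                       ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Simulate an ABC reference table of ``M`` draws and summary vectors."""
    rng = np.random.default_rng(seed)
    draws = sample_priors(priors, M, rng=rng)
    sims = []
    names: list[str] = []
    for _, row in draws.iterrows():
        model = draw_to_model(row)
        spec = SimSpec(n_o=n_target, n_c=n_source, n_loci=n_loci,
                       mu_msat=mu_msat, seed=int(rng.integers(2 ** 31)))
        tab = simulate_dataset(model, spec, rng)
        sv = compute_summaries(tab, "continental", ["orkney"])
        sims.append(sv.values)
        names = sv.names
    return draws, np.array(sims), names


def abc_fit(observed: SummaryVector, draws: pd.DataFrame,
            summaries: np.ndarray, tolerance: float,
            seed: int = 0) -> ABCResult:
    """Rejection step + posterior modes given a precomputed reference table."""
    retained, distances = abc_reject(observed.values, summaries, tolerance)
    modes = {p: posterior_mode(draws[p].to_numpy()[retained]) for p in PARAMS}
    return ABCResult(draws=draws, summaries=summaries,
                     summary_names=observed.names, distances=distances,
                     retained=retained, modes=modes, tolerance=tolerance,
                     seed=seed)


# ---------------------------------------------------------------------------
# Delta_C source ranking
# ---------------------------------------------------------------------------

def delta_c(table: GenotypeTable, candidate_pop: str, target_pops: list[str],
            priors: PriorSpec, n_sim: int, seed: int,
            mu_msat: float = 2e-4, min_n: int = 19,
            force: bool = False) -> float:
    """Mean standardized distance of the observed summaries to ``n_sim``
    colonization-model simulations with ``candidate_pop`` as source.

    For each target population the summary vector (candidate vs target) is
    compared to simulations with matching sample sizes; distances are
    standardized by the MAD of the simulated set and averaged over
    simulations and targets.  Candidates below ``min_n`` individuals are
    refused unless ``force``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    n_cand = int(table.pop_mask(candidate_pop).sum())
    if n_cand < min_n and not force:
        raise ValueError(
            f"candidate {candidate_pop!r} has n={n_cand} < {min_n}; "
            "pass force=True to rank it anyway")
    rng = np.random.default_rng(seed)
    per_target = []
    for target in target_pops:
        obs = compute_summaries(table, candidate_pop, [target])
        n_targ = int(table.pop_mask(target).sum())
        draws = sample_priors(priors, n_sim, rng=rng)
        sims = []
        for _, row in draws.iterrows():
            model = draw_to_model(row)
            spec = SimSpec(n_o=n_targ, n_c=n_cand, n_loci=len(table.loci),
                           mu_msat=mu_msat, seed=int(rng.integers(2 ** 31)))
            tab = simulate_dataset(model, spec, rng)
            sims.append(compute_summaries(tab, "continental",
                                          ["orkney"]).values)
        sims = np.array(sims)
        mad = np.median(np.abs(sims - np.median(sims, axis=0)), axis=0)
        keep = mad > 0
        z = (sims[:, keep] - obs.values[keep]) / mad[keep]
        per_target.append(float(np.sqrt((z ** 2).sum(axis=1)).mean()))
    return float(np.mean(per_target))


@dataclass
class SourceRankTable:
    """Delta_C per candidate with ascending ranks."""
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def rank_sources(deltas: dict[str, float],
                 sample_sizes: dict[str, int]) -> SourceRankTable:
    """Ascending Delta_C ranking; ties broken by larger n, then label."""
    if len(deltas) < 2:
        raise ValueError("need >= 2 candidates")
    rows = sorted(deltas.items(),
                  key=lambda kv: (kv[1], -sample_sizes.get(kv[0], 0), kv[0]))
    df = pd.DataFrame({
        "candidate": [r[0] for r in rows],
        "n": [sample_sizes.get(r[0], 0) for r in rows],
        "delta_c": [r[1] for r in rows],
        "rank": np.arange(1, len(rows) + 1),
    })
    return SourceRankTable(table=df)
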