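"""Coalescent simulation under the island-colonization demography.

The demographic model has 11 parameters: the two current diploid sizes
(continental ``N_c`` and island ``N_o``), the colonization/divergence time
``T_col`` (generations before present), a founder bottleneck of size ``N_f``
lasting ``d_f`` generations immediately after colonization (so occupying the
backwards-time interval ``[T_col - d_f, T_col)`` on the island branch), a
later island bottleneck ``(T_ob, N_ob, d_ob)`` and a continental bottleneck
``(T_cb, N_cb, d_cb)`` which may fall before or after the colonization.
Every bottleneck ends in an instantaneous (step) recovery — there are no
exponential-growth phases.

Genealogies follow the Kingman coalescent with pairwise rate ``1/(2N(t))``
per generation within each population; at ``T_col`` all island lineages join
the continental population, and there is no migration (an optional symmetric
rate is provided for sensitivity analysis).  Microsatellites mutate under a
strict symmetric stepwise model (SMM) from a root allele of 100, with
reflecting bounds [50, 150]; sequences mutate under infinite sites mapped
onto distinct columns of an all-A background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypeTable, SequenceAlignment

log = logging.getLogger(__name__)

ROOT_ALLELE = 100
ALLELE_BOUNDS = (50, 150)


@dataclass
class DemographicModel:
    """The 11-parameter two-population colonization scenario."""
    N_c: float                 # current continental diploid size
    N_o: float                 # current island diploid size
    T_col: float               # colonization time, generations BP
    N_f: float                 # founder-bottleneck size ...
    d_f: float                 # ... and duration (ends at T_col, forwards)
    T_ob: float = 0.0          # later island bottleneck: onset (backwards)
    N_ob: float = 2.0
    d_ob: float = 0.0
    T_cb: float = 0.0          # continental bottleneck: onset (backwards)
    N_cb: float = 2.0
    d_cb: float = 0.0
    migration: float = 0.0     # optional symmetric migration (per lineage/gen)

    def validate(self) -> None:
        for name in ("N_c", "N_o", "N_f", "N_ob", "N_cb"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("T_col", "T_ob", "T_cb", "d_f", "d_ob", "d_cb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.T_ob + self.d_ob > self.T_col - self.d_f + 1e-9:
            raise ValueError("island bottleneck overlaps the founder phase "
                             "(need T_ob + d_ob <= T_col - d_f)")

    @classmethod
    def param_names(cls) -> list[str]:
        return ["N_c", "N_o", "T_col", "N_f", "d_f",
                "T_ob", "N_ob", "d_ob", "T_cb", "N_cb", "d_cb"]

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.param_names()}


@dataclass
class SimSpec:
    """Sampling layout for one simulated dataset."""
    n_o: int                   # island diploid individuals
    n_c: int                   # continental diploid individuals
    n_loci: int
    mu_msat: float             # per-locus per-generation SMM rate
    seed: int

    def __post_init__(self) -> None:
        if self.n_o < 0 or self.n_c < 0 or self.n_o + self.n_c < 1:
            raise ValueError("need at least one sampled individual")
        if self.n_loci < 1 or self.mu_msat < 0:
            raise ValueError("n_loci >= 1 and mu_msat >= 0 required")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class Genealogy:
    """A coalescent tree: node times (generations) and parent pointers.

    Nodes ``0..n_tips-1`` are tips (time 0); internal nodes are appended in
    coalescence order; the root's parent is -1.
    """
    times: np.ndarray
    parent: np.ndarray
    n_tips: int
    tip_pops: list[str]

    @property
    def tmrca(self) -> float:
        return float(self.times.max())

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.times))
        has_parent = self.parent >= 0
        bl[has_parent] = self.times[self.parent[has_parent]] - \
            self.times[has_parent]
        return bl


# ---------------------------------------------------------------------------
# size trajectories
# ---------------------------------------------------------------------------

def size_trajectory(model: DemographicModel, pop: str
                    ) -> list[tuple[float, float, float]]:
    """Piecewise-constant backwards-time sizes ``(start, end, N)``.

    The island trajectory ends at ``T_col`` (after which the merged
    population takes the continental trajectory); the continental trajectory
    extends to infinity.
    """
    model.validate()
    if pop == "orkney":
        cuts: list[tuple[float, float, float]] = []
        t = 0.0
        if model.d_ob > 0 and model.T_ob < model.T_col:
            cuts.append((model.T_ob, model.T_ob + model.d_ob, model.N_ob))
        if model.d_f > 0:
            cuts.append((model.T_col - model.d_f, model.T_col, model.N_f))
        pieces = []
        for start, end, size in sorted(cuts):
            if start > t:
                pieces.append((t, start, model.N_o))
            pieces.append((start, end, size))
            t = end
        if t < model.T_col:
            pieces.append((t, model.T_col, model.N_o))
        return pieces
    if pop == "continental":
        pieces = []
        t = 0.0
        if model.d_cb > 0:
            if model.T_cb > 0:
                pieces.append((0.0, model.T_cb, model.N_c))
            pieces.append((model.T_cb, model.T_cb + model.d_cb, model.N_cb))
            t = model.T_cb + model.d_cb
        pieces.append((t, math.inf, model.N_c))
        return pieces
    raise ValueError(f"unknown population {pop!r}")


def _size_at(pieces: list[tuple[float, float, float]], t: float) -> float:
    for start, end, size in pieces:
        if start <= t < end:
            return size
    return pieces[-1][2]


def _next_boundary(pieces: list[tuple[float, float, float]], t: float) -> float:
    for start, end, _ in pieces:
        if t < start:
            return start
        if t < end:
            return end
    return math.inf


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

def _coalesce_interval(active: list[int], traj, t: float, t_stop: float,
                       times: np.ndarray, parent: np.ndarray, nxt: int,
                       rng: np.random.Generator) -> tuple[list[int], int]:
    """Coalesce ``active`` lineages on [t, t_stop) under a size trajectory.

    Exponential waiting times; size change points are event boundaries
    (memorylessness makes redrawing at a boundary exact).  Mutates ``times``
    and ``parent`` in place; returns the surviving lineages and the next
    free node index.
    """
    while len(active) > 1 and t < t_stop:
        N = _size_at(traj, t)
        kk = len(active)
        rate = kk * (kk - 1) / (4.0 * N)            # C(k,2) / (2N)
        bound = min(_next_boundary(traj, t), t_stop)
        wait = rng.exponential(1.0 / rate)
        if t + wait >= bound:
            t = bound
            continue
        t += wait
        i = rng.integers(kk)
        j = rng.integers(kk - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        times[nxt] = t
        parent[a] = parent[b] = nxt
        # swap-with-last removal keeps each event O(1)
        if i < j:
            i, j = j, i
        active[i] = active[-1]
        active.pop()
        active[j] = active[-1]
        active.pop()
        active.append(nxt)
        nxt += 1
    return active, nxt


def simulate_genealogy(model: DemographicModel, spec: SimSpec,
                       rng: np.random.Generator | None = None) -> Genealogy:
    """One genealogy of ``2*(n_o + n_c)`` gene copies under the model.

    Exponential waiting times between coalescences, with population-size
    change points treated as event boundaries; island lineages move to the
    continental side at ``T_col``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    model.validate()
    n_tips = 2 * (spec.n_o + spec.n_c)
    times = np.zeros(2 * n_tips - 1)
    parent = np.full(2 * n_tips - 1, -1, dtype=np.int64)
    tip_pops = ["orkney"] * (2 * spec.n_o) + ["continental"] * (2 * spec.n_c)
    ork = list(range(2 * spec.n_o))
    cont = list(range(2 * spec.n_o, n_tips))
    nxt = n_tips

    traj_c = size_trajectory(model, "continental")
    if ork:
        traj_o = size_trajectory(model, "orkney")
        ork, nxt = _coalesce_interval(ork, traj_o, 0.0, model.T_col,
                                      times, parent, nxt, rng)
    if cont:
        cont, nxt = _coalesce_interval(cont, traj_c, 0.0, model.T_col,
                                       times, parent, nxt, rng)
    merged = ork + cont
    _coalesce_interval(merged, traj_c, model.T_col, math.inf,
                       times, parent, nxt, rng)
    return Genealogy(times=times, parent=parent, n_tips=n_tips,
                     tip_pops=tip_pops)


# ---------------------------------------------------------------------------
# mutation models
# ---------------------------------------------------------------------------

_WARNED_BOUNDS: set[tuple[int, int]] = set()


def _fold(v: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Reflect an unbounded walk endpoint into [lo, hi] (method of images)."""
    period = 2 * (hi - lo)
    x = np.mod(v - lo, period)
    x = np.where(x > hi - lo, period - x, x)
    return lo + x


def mutate_smm(gen: Genealogy, mu_msat: float,
               rng: np.random.Generator | None = None,
               seed: int | None = None,
               bounds: tuple[int, int] = ALLELE_BOUNDS) -> np.ndarray:
    """Stepwise-mutation allele sizes at the tips.

    Poisson(mu * branch) mutations per branch, each +-1 repeat with equal
    probability; the root allele is 100 and sizes are reflected into
    ``bounds``.
    """
    if mu_msat < 0:
        raise ValueError("mu_msat must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    bl = gen.branch_lengths()
    m = rng.poisson(mu_msat * bl)
    net = 2 * rng.binomial(m, 0.5) - m
    # accumulate root-to-node displacement; parents coalesce later, so a
    # time-descending sweep sees every parent before its children
    disp = np.zeros(len(bl), dtype=np.int64)
    order = np.argsort(times_key := gen.times)[::-1]
    del times_key
    for v in order:
        p = gen.parent[v]
        if p >= 0:
            disp[v] = disp[p] + net[v]
    raw = ROOT_ALLELE + disp[:gen.n_tips]
    lo, hi = bounds
    if (raw < lo).any() or (raw > hi).any():
        if bounds not in _WARNED_BOUNDS:        # warn once per bound setting
            _WARNED_BOUNDS.add(bounds)
            log.warning("SMM allele sizes hit the bounds %s; reflected "
                        "(warning shown once)", bounds)
    return _fold(raw, lo, hi)


def simulate_dataset(model: DemographicModel, spec: SimSpec,
                     rng: np.random.Generator | None = None) -> GenotypeTable:
    """A diploid genotype table: ``n_loci`` independent SMM genealogies.

    Gene copies ``(2i, 2i+1)`` are paired into individuals, which — tips
    being exchangeable within a population — is a random pairing.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_ind = spec.n_o + spec.n_c
    alleles = np.empty((n_ind, spec.n_loci, 2), dtype=np.int64)
    for locus in range(spec.n_loci):
        gen = simulate_genealogy(model, spec, rng)
        tips = mutate_smm(gen, spec.mu_msat, rng)
        alleles[:, locus, :] = tips.reshape(n_ind, 2)
    individuals = [f"o{i + 1}" for i in range(spec.n_o)] + \
                  [f"c{i + 1}" for i in range(spec.n_c)]
    pops = {ind: ("orkney" if ind.startswith("o") else "continental")
            for ind in individuals}
    loci = [f"L{j + 1}" for j in range(spec.n_loci)]
    return GenotypeTable(individuals, pops, loci, alleles)


# ---------------------------------------------------------------------------
# sequences (infinite sites)
# ---------------------------------------------------------------------------

@dataclass
class SuddenGrowth:
    """Single-population step-change history for sequence simulation.

    Present size ``N1`` back to ``t_change`` generations BP, then ``N0``.
    ``N1/N0`` is the growth factor of a sudden expansion.
    """
    N1: float
    N0: float
    t_change: float

    def pieces(self) -> list[tuple[float, float, float]]:
        if self.t_change <= 0 or self.N1 == self.N0:
            return [(0.0, math.inf, self.N1)]
        return [(0.0, self.t_change, self.N1),
                (self.t_change, math.inf, self.N0)]


def _single_pop_genealogy(pieces, n: int, rng: np.random.Generator) -> Genealogy:
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    _coalesce_interval(list(range(n)), pieces, 0.0, math.inf,
                       times, parent, n, rng)
    return Genealogy(times=times, parent=parent, n_tips=n, tip_pops=["all"] * n)


def simulate_sequences(model_or_growth, n, L: int, mu_site: float,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> SequenceAlignment:
    """Infinite-sites sequences on a coalescent genealogy.

    ``model_or_growth`` is a :class:`SuddenGrowth` (then ``n`` is the sample
    size) or a :class:`DemographicModel` (then ``n`` is ``(n_o, n_c)``
    diploid individuals and both populations are sequenced).  Mutations are
    Poisson(mu_site * L * branch) per branch, each assigned to a distinct
    uniformly drawn column of an all-A alignment of length ``L``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(model_or_growth, SuddenGrowth):
        gen = _single_pop_genealogy(model_or_growth.pieces(), int(n), rng)
    else:
        n_o, n_c = n
        spec = SimSpec(n_o=n_o, n_c=n_c, n_loci=1, mu_msat=0.0,
                       seed=int(rng.integers(2 ** 31)))
        gen = simulate_genealogy(model_or_growth, spec, rng)

    bl = gen.branch_lengths()
    muts = rng.poisson(mu_site * L * bl)
    total = int(muts.sum())
    if total > L:
        raise ValueError(
            f"{total} mutations exceed L={L}; increase L or lower mu_site")
    cols = rng.choice(L, size=total, replace=False)
    # tips below each node
    children: dict[int, list[int]] = {}
    for v, p in enumerate(gen.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(v)
    tipsets: dict[int, list[int]] = {}

    def tips_below(v: int) -> list[int]:
        if v < gen.n_tips:
            return [v]
        if v not in tipsets:
            out: list[int] = []
            for c in children.get(v, []):
                out.extend(tips_below(c))
            tipsets[v] = out
        return tipsets[v]

    seqs = np.full((gen.n_tips, L), "A", dtype="U1")
    ci = 0
    bases = np.array(["C", "G", "T"])
    for v in range(len(bl)):
        for _ in range(int(muts[v])):
            col = cols[ci]
            ci += 1
            derived = bases[rng.integers(3)]
            seqs[tips_below(v), col] = derived
    ids = [f"s{i + 1}" for i in range(gen.n_tips)]
    pops = {i: p for i, p in zip(ids, gen.tip_pops)}
    return SequenceAlignment(ids, pops, seqs)
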