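"""Coalescent simulator: analytic expectations, structure, msprime oracle."""

import math

import numpy as np
import pytest

from island_ark import seqstats as ss
from island_ark.coalsim import (ALLELE_BOUNDS, ROOT_ALLELE, DemographicModel,
                                SimSpec, SuddenGrowth, _fold,
                                simulate_dataset, simulate_genealogy,
                                simulate_sequences, mutate_smm,
                                size_trajectory)


def flat_model(N=1000, T_col=0.0) -> DemographicModel:
    return DemographicModel(N_c=N, N_o=N, T_col=T_col, N_f=2, d_f=0)


# ---------------------------------------------------------------------------
# size trajectories
# ---------------------------------------------------------------------------

class TestSizeTrajectory:
    def test_no_bottlenecks_constant(self):
        m = DemographicModel(N_c=500, N_o=200, T_col=100, N_f=2, d_f=0)
        assert size_trajectory(m, "orkney") == [(0.0, 100, 200)]
        assert size_trajectory(m, "continental") == [(0.0, math.inf, 500)]

    def test_island_bottleneck_gives_three_pieces(self):
        m = DemographicModel(N_c=500, N_o=200, T_col=1000, N_f=2, d_f=0,
                             T_ob=100, N_ob=10, d_ob=50)
        pieces = size_trajectory(m, "orkney")
        assert pieces == [(0.0, 100, 200), (100, 150, 10), (150, 1000, 200)]

    def test_founder_phase_ends_at_colonization(self):
        m = DemographicModel(N_c=500, N_o=200, T_col=1000, N_f=20, d_f=100)
        pieces = size_trajectory(m, "orkney")
        assert pieces[-1] == (900, 1000, 20)

    def test_overlapping_bottlenecks_rejected(self):
        m = DemographicModel(N_c=500, N_o=200, T_col=1000, N_f=20, d_f=100,
                             T_ob=850, N_ob=10, d_ob=100)
        with pytest.raises(ValueError, match="overlap"):
            m.validate()

    def test_coalescent_intensity_integrates_piecewise(self):
        """Pr(no coalescence by t) for n=2 matches the piecewise integral."""
        m = DemographicModel(N_c=500, N_o=100, T_col=4000, N_f=2, d_f=0,
                             T_ob=500, N_ob=10, d_ob=100)
        rng = np.random.default_rng(0)
        spec = SimSpec(n_o=1, n_c=0, n_loci=1, mu_msat=0, seed=1)
        t_probe = 700.0
        # hand integral of 1/(2N(t)) over [0, 700]
        intensity = 500 / 200 + 100 / 20 + 100 / 200
        expect = math.exp(-intensity)
        hits = sum(simulate_genealogy(m, spec, rng).tmrca > t_probe
                   for _ in range(4000)) / 4000
        assert hits == pytest.approx(expect, abs=4 * math.sqrt(
            expect * (1 - expect) / 4000))


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

class TestGenealogy:
    def test_pair_tmrca_mean_2N(self, rng):
        N = 800
        spec = SimSpec(n_o=0, n_c=1, n_loci=1, mu_msat=0, seed=1)
        t = [simulate_genealogy(flat_model(N), spec, rng).tmrca
             for _ in range(2000)]
        se = 2 * N / math.sqrt(2000)
        assert abs(np.mean(t) - 2 * N) < 3 * se

    def test_split_precedes_cross_population_coalescence(self, rng):
        m = DemographicModel(N_c=500, N_o=300, T_col=2000, N_f=10, d_f=20)
        spec = SimSpec(n_o=3, n_c=3, n_loci=1, mu_msat=0, seed=1)
        for _ in range(20):
            g = simulate_genealogy(m, spec, rng)
            # walk each island tip up; first ancestor shared with a
            # continental tip must be older than T_col
            anc = []
            for tip in range(g.n_tips):
                s, v = set(), tip
                while v != -1:
                    s.add(v)
                    v = g.parent[v]
                anc.append(s)
            for i in range(2 * 3):
                for j in range(2 * 3, g.n_tips):
                    mrca = min(anc[i] & anc[j], key=lambda v: g.times[v])
                    assert g.times[mrca] > m.T_col

    def test_seed_determinism(self):
        m = flat_model()
        spec = SimSpec(n_o=2, n_c=2, n_loci=1, mu_msat=0, seed=77)
        g1 = simulate_genealogy(m, spec)
        g2 = simulate_genealogy(m, spec)
        assert (g1.times == g2.times).all() and (g1.parent == g2.parent).all()

    def test_ultrametric_and_tip_count(self, rng):
        spec = SimSpec(n_o=2, n_c=3, n_loci=1, mu_msat=0, seed=1)
        g = simulate_genealogy(flat_model(), spec, rng)
        assert g.n_tips == 10
        assert (g.times[:g.n_tips] == 0).all()
        assert (np.sort(g.times[g.n_tips:]) > 0).all()
        assert (g.parent == -1).sum() == 1


# ---------------------------------------------------------------------------
# mutation models
# ---------------------------------------------------------------------------

class TestSmm:
    def test_zero_rate_keeps_root_allele(self, rng):
        spec = SimSpec(n_o=0, n_c=5, n_loci=1, mu_msat=0, seed=1)
        g = simulate_genealogy(flat_model(), spec, rng)
        assert (mutate_smm(g, 0.0, rng) == ROOT_ALLELE).all()

    def test_fold_reflects_into_bounds(self):
        lo, hi = ALLELE_BOUNDS
        assert _fold(np.array([hi + 3]), lo, hi)[0] == hi - 3
        assert _fold(np.array([lo - 2]), lo, hi)[0] == lo + 2
        assert _fold(np.array([75]), lo, hi)[0] == 75

    def test_equilibrium_homozygosity(self, rng):
        """Mean SMM homozygosity ~ 1/sqrt(1+2*theta), theta = 4*N*mu."""
        N, mu, loci = 250, 4e-4, 3000
        theta = 4 * N * mu
        expect = 1.0 / math.sqrt(1 + 2 * theta)
        spec = SimSpec(n_o=0, n_c=5, n_loci=1, mu_msat=mu, seed=1)
        m = flat_model(N)
        homs = np.empty(loci)
        for i in range(loci):
            tips = mutate_smm(simulate_genealogy(m, spec, rng), mu, rng)
            _, c = np.unique(tips, return_counts=True)
            p = c / len(tips)
            # unbiased pair-identity probability (the closed form's scale)
            k = len(tips)
            homs[i] = (k * (p ** 2).sum() - 1) / (k - 1)
        se = homs.std(ddof=1) / math.sqrt(loci)
        assert abs(homs.mean() - expect) < 3 * se + 0.01

    def test_single_terminal_mutation_moves_one_tip(self):
        from island_ark.coalsim import Genealogy
        g = Genealogy(times=np.array([0.0, 0.0, 100.0]),
                      parent=np.array([2, 2, -1]), n_tips=2,
                      tip_pops=["all", "all"])
        rng = np.random.default_rng(4)
        for _ in range(50):
            tips = mutate_smm(g, 1e-9, rng)
            assert set(np.abs(tips - ROOT_ALLELE)) <= {0, 1}


class TestDataset:
    def test_shape_and_labels(self):
        m = flat_model(T_col=10)
        spec = SimSpec(n_o=3, n_c=3, n_loci=2, mu_msat=1e-4, seed=5)
        t = simulate_dataset(m, spec)
        assert len(t.individuals) == 6 and len(t.loci) == 2
        assert t.populations == ["orkney", "continental"]
        assert (t.alleles != -1).all()

    def test_seed_reproducibility(self):
        m = flat_model(T_col=10)
        spec = SimSpec(n_o=2, n_c=2, n_loci=3, mu_msat=2e-4, seed=8)
        a = simulate_dataset(m, spec).alleles
        b = simulate_dataset(m, spec).alleles
        assert (a == b).all()

    def test_severe_founder_raises_fst(self, rng):
        """Deep split + tiny founder gives larger F_ST than no split."""
        from island_ark.msatstats import fst
        severe = DemographicModel(N_c=2000, N_o=500, T_col=3000, N_f=10,
                                  d_f=20)
        mild = DemographicModel(N_c=2000, N_o=2000, T_col=1, N_f=2000, d_f=0)
        vals = {}
        for name, m in (("severe", severe), ("mild", mild)):
            acc = []
            for rep in range(30):
                spec = SimSpec(n_o=8, n_c=8, n_loci=6, mu_msat=2e-4,
                               seed=1000 + rep)
                acc.append(fst(simulate_dataset(m, spec)).overall)
            vals[name] = np.mean(acc)
        assert vals["severe"] > vals["mild"] + 0.1

    def test_panmixia_limit(self):
        """T_col -> 0 without bottlenecks behaves like one population."""
        from island_ark.msatstats import fst
        m = DemographicModel(N_c=1000, N_o=1000, T_col=0, N_f=2, d_f=0)
        acc = []
        for rep in range(40):
            spec = SimSpec(n_o=6, n_c=6, n_loci=8, mu_msat=3e-4,
                           seed=2000 + rep)
            acc.append(fst(simulate_dataset(m, spec)).overall)
        assert abs(np.mean(acc)) < 0.03


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

class TestSequences:
    def test_zero_rate_identical(self, rng):
        aln = simulate_sequences(SuddenGrowth(500, 500, 0), 6, 100, 0.0,
                                 rng=rng)
        assert len({"".join(r) for r in aln.seqs}) == 1

    def test_watterson_expectation(self, rng):
        """Mean S ~ theta * a1 under constant size (theta = 4*N*u)."""
        N, mu, L, n = 500, 2.5e-6, 1000, 20
        theta = 4 * N * mu * L
        a1 = sum(1 / i for i in range(1, n))
        reps = 300
        S = np.empty(reps)
        for i in range(reps):
            aln = simulate_sequences(SuddenGrowth(N, N, 0), n, L, mu, rng=rng)
            S[i] = ss.segregating_sites(aln)
        se = S.std(ddof=1) / math.sqrt(reps)
        assert abs(S.mean() - theta * a1) < 3 * se

    def test_too_many_mutations_errors(self, rng):
        with pytest.raises(ValueError, match="increase L"):
            simulate_sequences(SuddenGrowth(5000, 5000, 0), 10, 5, 0.1,
                               rng=rng)

    def test_two_population_mode(self, rng):
        m = DemographicModel(N_c=500, N_o=200, T_col=500, N_f=10, d_f=10)
        aln = simulate_sequences(m, (2, 3), 500, 1e-6, rng=rng)
        assert aln.n == 10
        assert sum(p == "orkney" for p in aln.pops.values()) == 4


# ---------------------------------------------------------------------------
# independent oracle: msprime
# ---------------------------------------------------------------------------

class TestMsprimeCrossCheck:
    """TMRCA distributions for benchmark demographies vs msprime."""

    REPS = 300

    def _ours(self, model, n_o, n_c, rng):
        spec = SimSpec(n_o=n_o, n_c=n_c, n_loci=1, mu_msat=0, seed=1)
        return np.array([simulate_genealogy(model, spec, rng).tmrca
                         for _ in range(self.REPS)])

    def _msprime_constant(self, N, n, rng):
        import msprime
        return np.array([
            msprime.sim_ancestry(samples=n, population_size=N, ploidy=2,
                                 random_seed=int(rng.integers(1, 2 ** 31))
                                 ).max_root_time
            for _ in range(self.REPS)])

    def test_constant_size(self, rng):
        ours = self._ours(flat_model(400), 0, 4, rng)
        oracle = self._msprime_constant(400, 4, rng)
        se = math.hypot(ours.std(ddof=1), oracle.std(ddof=1)) \
            / math.sqrt(self.REPS)
        assert abs(ours.mean() - oracle.mean()) < 3 * se

    def test_bottleneck(self, rng):
        import msprime
        m = DemographicModel(N_c=1000, N_o=2, T_col=0, N_f=2, d_f=0,
                             T_cb=200, N_cb=50, d_cb=100)
        ours = self._ours(m, 0, 4, rng)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=1000)
        dem.add_population_parameters_change(time=200, initial_size=50,
                                             population="A")
        dem.add_population_parameters_change(time=300, initial_size=1000,
                                             population="A")
        oracle = np.array([
            msprime.sim_ancestry(samples={"A": 4}, demography=dem, ploidy=2,
                                 random_seed=int(rng.integers(1, 2 ** 31))
                                 ).max_root_time
            for _ in range(self.REPS)])
        se = math.hypot(ours.std(ddof=1), oracle.std(ddof=1)) \
            / math.sqrt(self.REPS)
        assert abs(ours.mean() - oracle.mean()) < 3 * se

    def test_two_population_split(self, rng):
        import msprime
        m = DemographicModel(N_c=800, N_o=300, T_col=1000, N_f=300, d_f=0)
        ours = self._ours(m, 3, 3, rng)
        dem = msprime.Demography()
        dem.add_population(name="cont", initial_size=800)
        dem.add_population(name="ork", initial_size=300)
        dem.add_population(name="anc", initial_size=800)
        dem.add_population_split(time=1000, derived=["cont", "ork"],
                                 ancestral="anc")
        oracle = np.array([
            msprime.sim_ancestry(samples={"ork": 3, "cont": 3},
                                 demography=dem, ploidy=2,
                                 random_seed=int(rng.integers(1, 2 ** 31))
                                 ).max_root_time
            for _ in range(self.REPS)])
        se = math.hypot(ours.std(ddof=1), oracle.std(ddof=1)) \
            / math.sqrt(self.REPS)
        assert abs(ours.mean() - oracle.mean()) < 3 * se
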