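"""Synthetic-data generators with known ground truth.

Each generator returns a :class:`SyntheticStudy` bundling the generated
data, the generating parameters ("truth") and the seed, and can write the
data in its standard on-disk format (GenePop / FASTA / TPS) next to a
``truth.yaml`` so the whole pipeline — including the file readers — is
exercisable without any downloaded data.  Regeneration from (truth, seed)
is bit-identical.

Defaults mirror the study layout this package models: 14 microsatellite
loci, island samples of 19-26 individuals, a colonization ~5000 generations
ago through a ~20-individual founder bottleneck, sequence sets of n = 68 at
L = 1143 sites, and 18 fixed landmarks + 12 semi-landmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .coalsim import (DemographicModel, SimSpec, SuddenGrowth,
                      simulate_dataset, simulate_sequences)
from .io_formats import (GenotypeTable, LandmarkDataset, SequenceAlignment,
                         write_fasta, write_genotypes, write_tps)

log = logging.getLogger(__name__)

#: island sample sizes of the three best-sampled island populations
DEFAULT_ISLAND_SIZES = (23, 26, 19)
DEFAULT_SOURCE_SIZE = 26
DEFAULT_N_LOCI = 14
DEFAULT_MU_MSAT = 2e-4
DEFAULT_MU_SITE = 3.27e-7


@dataclass
class SyntheticStudy:
    """Generated data plus the parameters that generated it."""
    kind: str
    truth: dict
    data: object
    seed: int

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write data in its standard format plus truth.yaml; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        if isinstance(self.data, GenotypeTable):
            p = outdir / f"{self.kind}.genepop"
            write_genotypes(self.data, p, dialect="genepop")
        elif isinstance(self.data, SequenceAlignment):
            p = outdir / f"{self.kind}.fasta"
            write_fasta(self.data, p)
        elif isinstance(self.data, LandmarkDataset):
            p = outdir / f"{self.kind}.tps"
            write_tps(self.data, p)
        else:                                     # pragma: no cover
            raise TypeError(f"cannot serialise {type(self.data)}")
        paths["data"] = str(p)
        tp = outdir / "truth.yaml"
        tp.write_text(yaml.safe_dump(
            {"kind": self.kind, "seed": self.seed, "truth": self.truth}))
        paths["truth"] = str(tp)
        return paths


def default_colonization_model() -> DemographicModel:
    """The reference colonization scenario used as generator truth.

    Sizes are set so that, at the default SMM rate (2e-4 per locus per
    generation), equilibrium heterozygosity matches the diversity levels
    typical of the system this emulates (source H ~ 0.7, island H ~
    0.4-0.6): theta = 4 N mu gives theta ~ 6 for the continental source and
    ~ 1.5 for the island, with a ~30-founder colonization 5000 generations
    ago followed by rapid growth.
    """
    return DemographicModel(N_c=7500, N_o=1875, T_col=5000, N_f=30, d_f=10)


def synth_colonization(seed: int,
                       model: DemographicModel | None = None,
                       island_sizes: tuple[int, ...] = DEFAULT_ISLAND_SIZES,
                       source_size: int = DEFAULT_SOURCE_SIZE,
                       n_loci: int = DEFAULT_N_LOCI,
                       mu_msat: float = DEFAULT_MU_MSAT) -> SyntheticStudy:
    """A genotype table with one source and several island populations.

    The island populations are labelled subsamples of one simulated island
    sample (they are panmictic post-colonization), mirroring a source +
    several colonized localities layout.
    """
    model = model or default_colonization_model()
    n_island = int(sum(island_sizes))
    spec = SimSpec(n_o=n_island, n_c=source_size, n_loci=n_loci,
                   mu_msat=mu_msat, seed=seed)
    table = simulate_dataset(model, spec)
    pops = dict(table.pops)
    names = [f"island{i + 1}" for i in range(len(island_sizes))]
    idx = 0
    for name, size in zip(names, island_sizes):
        for _ in range(size):
            pops[table.individuals[idx]] = name
            idx += 1
    for ind in table.individuals[n_island:]:
        pops[ind] = "source"
    table = GenotypeTable(list(table.individuals), pops, list(table.loci),
                          table.alleles)
    truth = {"model": model.as_dict(), "island_sizes": list(island_sizes),
             "source_size": source_size, "n_loci": n_loci, "mu_msat": mu_msat}
    return SyntheticStudy(kind="colonization", truth=truth, data=table,
                          seed=seed)


def synth_expansion_alignment(n: int = 68, theta0: float = 0.5,
                              growth_factor: float = 100.0,
                              t_growth: float = 1860.0, L: int = 1143,
                              seed: int = 0,
                              mu_site: float = DEFAULT_MU_SITE
                              ) -> SyntheticStudy:
    """A coalescent alignment under sudden growth; truth records tau.

    theta0 is the pre-expansion 2*N0*u (u = per-sequence rate mu_site * L);
    the population steps to ``growth_factor * N0`` at ``t_growth``
    generations BP, so the implied mismatch parameter is
    tau = 2 u t_growth.
    """
    if growth_factor < 1:
        raise ValueError("growth_factor must be >= 1")
    u = mu_site * L
    N0 = theta0 / (4.0 * u)          # diploid size: theta = 4 N u
    growth = SuddenGrowth(N1=growth_factor * N0, N0=max(N0, 2.0),
                          t_change=t_growth)
    aln = simulate_sequences(growth, n, L, mu_site, seed=seed)
    truth = {"n": n, "theta0": theta0, "growth_factor": growth_factor,
             "t_growth": t_growth, "L": L, "mu_site": mu_site,
             "tau": 2.0 * u * t_growth}
    return SyntheticStudy(kind="expansion", truth=truth, data=aln, seed=seed)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _template(k_fixed: int, k_semi: int) -> np.ndarray:
    """A tooth-like template: an elliptical crown plus an anterior-loop arc."""
    ang = np.linspace(0, 2 * np.pi, k_fixed, endpoint=False)
    fixed = np.column_stack([np.cos(ang), 0.6 * np.sin(ang)])
    arc = np.linspace(-0.45 * np.pi, 0.45 * np.pi, k_semi)
    semi = np.column_stack([1.0 + 0.35 * np.cos(arc), 0.35 * np.sin(arc)])
    return np.vstack([fixed, semi])


def _deformation_field(template: np.ndarray) -> np.ndarray:
    """A fixed, smooth, unit-norm displacement field (broadens the loop)."""
    x, y = template[:, 0], template[:, 1]
    field = np.column_stack([0.3 * x ** 2, y * (1 + 0.5 * x)])
    field -= field.mean(axis=0)
    return field / np.linalg.norm(field)


def synth_landmarks(n_per_group: int = 20, k_fixed: int = 18,
                    k_semi: int = 12, effect_size: float = 0.1,
                    size_ratio: float = 1.2, noise_sd: float = 0.005,
                    seed: int = 0) -> SyntheticStudy:
    """Two-group landmark sets with known shape offset and size ratio.

    Group "island" is displaced along a fixed deformation field scaled by
    ``effect_size`` and magnified by ``size_ratio``; every specimen gets
    isotropic Gaussian digitizing noise and a random rotation/translation.
    """
    if k_fixed < 3:
        raise ValueError("k_fixed must be >= 3")
    rng = np.random.default_rng(seed)
    template = _template(k_fixed, k_semi)
    field = _deformation_field(template)
    k = k_fixed + k_semi
    specimens, coords, groups = [], [], {}
    for gi, gname in enumerate(("continental", "island")):
        base = template + (effect_size * field if gname == "island" else 0.0)
        scale = size_ratio if gname == "island" else 1.0
        for i in range(n_per_group):
            cfg = scale * (base + rng.normal(0, noise_sd, size=(k, 2)))
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            cfg = cfg @ R.T + rng.uniform(-5, 5, size=2)
            name = f"{gname}{i + 1}"
            specimens.append(name)
            coords.append(cfg)
            groups[name] = gname
    semi_flags = np.zeros(k, dtype=bool)
    semi_flags[k_fixed:] = True
    ds = LandmarkDataset(specimens, np.array(coords), semi_flags,
                         list(range(k_fixed, k)), groups)
    truth = {"n_per_group": n_per_group, "k_fixed": k_fixed, "k_semi": k_semi,
             "effect_size": effect_size, "size_ratio": size_ratio,
             "noise_sd": noise_sd}
    return SyntheticStudy(kind="landmarks", truth=truth, data=ds, seed=seed)


# ---------------------------------------------------------------------------
# ranking studies (for Delta_C recovery experiments)
# ---------------------------------------------------------------------------

def synth_source_ranking(seed: int,
                         model: DemographicModel | None = None,
                         n_candidate: int = 24,
                         island_sizes: tuple[int, ...] = (20, 20),
                         T_sister: float = 10000.0,
                         N_sister: float = 2000.0,
                         T_outgroup: float = 20000.0,
                         N_outgroup: float = 500.0,
                         n_loci: int = DEFAULT_N_LOCI,
                         mu_msat: float = DEFAULT_MU_MSAT) -> SyntheticStudy:
    """A table where the islands truly descend from candidate "true_source".

    One joint four-deme coalescent history: the islands split from the true
    source at ``T_col`` (with the founder bottleneck), a smaller regional
    "sister" deme split from the same source lineage at ``T_sister``, and a
    small distant "outgroup" deme split at ``T_outgroup`` — the candidate
    panel used to check that Delta_C ranks the real source first.
    ``T_sister`` must predate the colonization (``T_sister > T_col``): a
    deme that separated afterwards is genealogically exchangeable with the
    source, and under the stepwise mutation model an equal-size deme remains
    nearly exchangeable even for much older splits (homoplasy compresses
    F_ST at these timescales), so the decoys differ in size as real regional
    demes do.
    """
    from .coalsim import (Genealogy, _coalesce_interval, mutate_smm,
                          size_trajectory)
    model = model or default_colonization_model()
    model.validate()
    if T_sister <= model.T_col or T_outgroup <= T_sister:
        raise ValueError("need T_outgroup > T_sister > T_col")
    rng = np.random.default_rng(seed)
    n_island = int(sum(island_sizes))
    counts = {"island": n_island, "true_source": n_candidate,
              "sister": n_candidate, "outgroup": n_candidate}
    n_tips = 2 * sum(counts.values())
    const = lambda N: [(0.0, np.inf, float(N))]  # noqa: E731
    traj = {"island": size_trajectory(model, "orkney"),
            "true_source": size_trajectory(model, "continental"),
            "sister": const(N_sister),
            "outgroup": const(N_outgroup)}

    def one_locus() -> np.ndarray:
        times = np.zeros(2 * n_tips - 1)
        parent = np.full(2 * n_tips - 1, -1, dtype=np.int64)
        lin, start = {}, 0
        for deme, n_ind in counts.items():
            lin[deme] = list(range(start, start + 2 * n_ind))
            start += 2 * n_ind
        nxt = n_tips
        # independent demes between merge events (no migration)
        lin["sister"], nxt = _coalesce_interval(
            lin["sister"], traj["sister"], 0.0, T_sister,
            times, parent, nxt, rng)
        lin["island"], nxt = _coalesce_interval(
            lin["island"], traj["island"], 0.0, model.T_col,
            times, parent, nxt, rng)
        lin["outgroup"], nxt = _coalesce_interval(
            lin["outgroup"], traj["outgroup"], 0.0, T_outgroup,
            times, parent, nxt, rng)
        src = lin["true_source"]
        src, nxt = _coalesce_interval(src, traj["true_source"], 0.0,
                                      model.T_col, times, parent, nxt, rng)
        src, nxt = _coalesce_interval(src + lin["island"],
                                      traj["true_source"], model.T_col,
                                      T_sister, times, parent, nxt, rng)
        src, nxt = _coalesce_interval(src + lin["sister"],
                                      traj["true_source"], T_sister,
                                      T_outgroup, times, parent, nxt, rng)
        _coalesce_interval(src + lin["outgroup"], traj["true_source"],
                           T_outgroup, np.inf, times, parent, nxt, rng)
        gen = Genealogy(times=times, parent=parent, n_tips=n_tips,
                        tip_pops=[])
        return mutate_smm(gen, mu_msat, rng)

    copies = np.stack([one_locus() for _ in range(n_loci)], axis=1)
    alleles = copies.reshape(n_tips // 2, 2, n_loci).transpose(0, 2, 1)
    individuals, pops = [], {}
    labels = []
    for pi, size in enumerate(island_sizes):
        labels += [f"island{pi + 1}"] * size
    labels += ["true_source"] * n_candidate
    labels += ["sister"] * n_candidate + ["outgroup"] * n_candidate
    for i, lab in enumerate(labels):
        name = f"{lab[0]}{i + 1}"
        individuals.append(name)
        pops[name] = lab
    table = GenotypeTable(individuals, pops,
                          [f"L{j + 1}" for j in range(n_loci)], alleles)
    truth = {"model": model.as_dict(), "true_source": "true_source",
             "targets": [f"island{i + 1}" for i in range(len(island_sizes))],
             "T_sister": T_sister, "N_sister": N_sister,
             "T_outgroup": T_outgroup,
             "N_outgroup": N_outgroup, "n_candidate": n_candidate,
             "n_loci": n_loci, "mu_msat": mu_msat}
    return SyntheticStudy(kind="ranking", truth=truth, data=table, seed=seed)
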