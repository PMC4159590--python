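import numpy as np
import pytest
from hypothesis import settings

from island_ark.io_formats import GenotypeTable, SequenceAlignment

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def make_alignment(rows: list[str], pops: dict[str, str] | None = None
                   ) -> SequenceAlignment:
    ids = [f"s{i + 1}" for i in range(len(rows))]
    pops = pops or {i: "all" for i in ids}
    return SequenceAlignment(ids, pops, np.array([list(r) for r in rows]))


def make_table(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
               loci: list[str] | None = None) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [per-individual locus pairs]}."""
    individuals, pops, rows = [], {}, []
    for pop, inds in pop_genotypes.items():
        for pairs in inds:
            name = f"{pop}_{len(individuals) + 1}"
            individuals.append(name)
            pops[name] = pop
            rows.append([list(p) for p in pairs])
    arr = np.array(rows)
    loci = loci or [f"L{j + 1}" for j in range(arr.shape[1])]
    return GenotypeTable(individuals, pops, loci, arr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_alignment():
    return make_alignment(["ACGT", "ACGA"])
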