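import numpy as np
import pytest

from msatdem.genepop import AUTOSOMAL, Dataset, Individual, LocusDef


def build_dataset(pop_blocks, loci=None, sexes=None):
    """Assemble a Dataset from {population: (n_ind, n_loci, 2) nested lists}.

    ``sexes`` optionally maps population -> list of sexes; default male.
    """
    first = next(iter(pop_blocks.values()))
    n_loci = len(first[0])
    if loci is None:
        loci = [LocusDef(f"L{j + 1}", AUTOSOMAL) for j in range(n_loci)]
    individuals, rows = [], []
    for pop, block in pop_blocks.items():
        sx = (sexes or {}).get(pop, ["male"] * len(block))
        for i, row in enumerate(block):
            individuals.append(Individual(f"{pop}-{i}", pop, sx[i]))
            rows.append(row)
    return Dataset(loci, individuals, np.asarray(rows, dtype=np.int32))


def random_dataset(rng, n_pops=2, max_ind=6, n_loci=3, n_alleles=4, missing_rate=0.1):
    """Small random diploid dataset for oracle comparisons."""
    blocks = {}
    for p in range(n_pops):
        n_ind = int(rng.integers(2, max_ind + 1))
        block = rng.integers(10, 10 + n_alleles, size=(n_ind, n_loci, 2))
        miss = rng.random((n_ind, n_loci)) < missing_rate
        block[miss] = 0
        blocks[f"P{p + 1}"] = block
    return build_dataset(blocks)


@pytest.fixture(scope="session")
def paper_fixture():
    from msatdem.synthetic import paper_shape_fixture

    return paper_shape_fixture(seed=1)
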