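import numpy as np
import pandas as pd
import pytest

from qstkit.data_io import MISSING, GenotypeTable


def build_genotypes(geno: dict[str, list[tuple]], loci: list[str]) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [((a1, a2), (a1, a2), ...), ...]}.

    Each individual is a tuple of per-locus allele pairs; None means missing.
    """
    individuals, populations, rows = [], [], []
    k = 0
    for pop, inds in geno.items():
        for ind in inds:
            k += 1
            individuals.append(f"i{k}")
            populations.append(pop)
            row = []
            for pair in ind:
                row.append((MISSING, MISSING) if pair is None else pair)
            rows.append(row)
    return GenotypeTable(individuals, populations, loci, np.asarray(rows))


def random_genotype_table(rng: np.random.Generator, n_pop=3, n_ind=4, n_loci=3):
    alleles = rng.integers(100, 140, size=(n_pop * n_ind, n_loci, 2)) * 2
    individuals = [f"p{p}_i{i}" for p in range(n_pop) for i in range(n_ind)]
    populations = [f"pop{p}" for p in range(n_pop) for _ in range(n_ind)]
    loci = [f"L{j}" for j in range(n_loci)]
    return GenotypeTable(individuals, populations, loci, alleles)


def nested_trait_data(
    rng: np.random.Generator,
    n_pop=6,
    n_fam=4,
    n_off=4,
    v_ap=1.0,
    v_wp=1.0,
    v_res=1.0,
    treatments=("T0",),
    trait="y",
) -> pd.DataFrame:
    """Minimal nested common-garden dataset with known variance components."""
    rows = []
    for p in range(n_pop):
        pop = f"pop{p}"
        pe = rng.normal(0, np.sqrt(v_ap))
        for f in range(n_fam):
            fam = f"{pop}_f{f}"
            fe = rng.normal(0, np.sqrt(v_wp))
            for t in treatments:
                for o in range(n_off):
                    rows.append({
                        "individual_id": f"{fam}_{t}_{o}",
                        "population_id": pop,
                        "seed_family_id": fam,
                        "treatment": t,
                        trait: pe + fe + rng.normal(0, np.sqrt(v_res)),
                    })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
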