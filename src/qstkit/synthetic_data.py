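"""Synthetic genotype, phenotype and soil data with the statistical
structure the analyses assume.

The genotype generator uses an island model: per locus, population allele
frequencies are drawn from a Dirichlet around base frequencies with
concentration (1 - F_ST) / F_ST, so the expected differentiation matches the
target F_ST; predominant selfing enters through the equilibrium inbreeding
coefficient F_IS = s / (2 - s), raising within-individual homozygosity.
Phenotypes follow the nested common-garden model (population, seed family,
family x treatment and residual variance components, treatment fixed
effects, optional soil cline).  A bundled 22-population study design (ids,
coordinates, admixture Q-vectors, gene diversity and the unbalanced
per-treatment family/offspring counts of a German *Juncus effusus*
common-garden panel) drives the paper-like fixture.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import GenotypeTable, TREATMENTS

# 22-population common-garden study design: latitude/longitude (decimal
# degrees), seed families / total individuals per nitrogen treatment
# ("-" = population absent from that treatment), three-cluster admixture
# Q-vector and population gene diversity.  SF1/SF2 are two co-occurring
# lineages sampled at one site and treated as separate populations.
_STUDY_DESIGN_CSV = """\
population_id,latitude,longitude,fam_t0,n_t0,fam_t70,n_t70,fam_t150,n_t150,q_eff1,q_eff2,q_eff3,he
BB,51.5117,11.9263,4,16,0,0,4,12,0.975,0.023,0.003,0.359
DB,51.8531,10.7057,5,14,0,0,0,0,0.116,0.877,0.007,0.356
EB,51.0320,11.2638,5,20,4,11,4,12,0.001,0.996,0.003,0.181
ES,51.4192,11.6676,6,24,4,12,4,12,0.001,0.998,0.001,0.042
ET,51.7475,10.6810,6,24,4,12,4,12,0.001,0.002,0.997,0.133
GF,50.7438,10.7914,6,24,4,12,4,12,0.997,0.002,0.001,0.256
GR,51.9124,11.9178,5,14,0,0,0,0,0.002,0.994,0.004,0.144
JAM,52.5029,11.4720,5,19,4,12,4,12,0.986,0.003,0.011,0.275
JEM,52.6365,11.2620,6,24,4,12,4,11,0.989,0.009,0.002,0.302
MS,51.0587,13.0458,5,20,0,0,4,12,0.005,0.989,0.006,0.075
OH,50.7150,10.7769,5,17,0,0,4,12,0.993,0.005,0.002,0.197
PWA,51.5739,12.7381,5,20,4,12,4,12,0.924,0.022,0.055,0.341
PWI,51.5655,12.7322,5,20,4,12,4,12,0.021,0.941,0.038,0.194
RB,51.7407,10.8875,5,16,0,0,0,0,0.002,0.002,0.996,0.027
RO,51.6114,12.4493,5,20,4,12,4,12,0.003,0.981,0.017,0.203
SC,51.7732,10.6388,6,22,0,0,0,0,0.002,0.002,0.996,0.250
SF1,51.6605,11.0484,4,16,0,0,0,0,0.996,0.002,0.002,0.188
SF2,51.6605,11.0484,5,20,0,0,0,0,0.002,0.997,0.001,0.050
WD,51.3017,12.9030,4,15,0,0,4,12,0.001,0.988,0.011,0.144
WL,51.8336,12.4348,5,20,4,12,4,12,0.024,0.967,0.010,0.181
ZM,50.6722,10.6739,5,20,4,12,4,12,0.997,0.001,0.002,0.000
ZR,51.3455,11.4931,4,14,4,12,4,12,0.002,0.996,0.002,0.198
"""

#: Soil variables emulating a LUCAS-style topsoil extract.
SOIL_VARIABLES = (
    "clay", "silt", "sand", "coarse_fragments", "ph", "organic_carbon",
    "carbonate", "phosphorus", "nitrogen", "potassium", "cec",
)


def study_design() -> pd.DataFrame:
    """The bundled 22-population study-design table (one row per population)."""
    return pd.read_csv(io.StringIO(_STUDY_DESIGN_CSV))


@dataclass
class SimDesign:
    """Generative parameters for one synthetic dataset.

    The defaults mirror the study conditions the analyses target: 22
    populations in three lineages (8/11/3), 5 seed families per population
    with 4 offspring per family and treatment, three nitrogen treatments,
    strong neutral differentiation (F_ST 0.66) under predominant selfing,
    and unit among-population / seed-family variances.
    """

    n_pop: int = 22
    lineage_partition: tuple[int, ...] = (8, 11, 3)
    families_per_population: int = 5
    offspring_per_family: int = 4
    treatments: tuple[str, ...] = TREATMENTS
    mask: dict | None = None  # pop -> {treatment: (n_families, n_individuals)}
    selfing_rate: float = 0.95
    target_fst: float = 0.66
    n_loci: int = 16
    n_alleles: int = 5
    n_ind_genotyped: int = 10
    grand_mean: float = 10.0
    treatment_effects: tuple[float, ...] = (0.0, 1.0, 2.0)
    v_ap: float = 1.0
    v_wp: float = 1.0
    v_ft: float = 0.25
    v_res: float = 1.0
    pc1_slope: float = 0.0
    gradient_weight: float = 1.0
    trait_name: str = "trait1"
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must lie in [0, 1]")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        for name in ("v_ap", "v_wp", "v_ft", "v_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mask is not None:
            for pop, treatments in self.mask.items():
                unknown = set(treatments) - set(self.treatments)
                if unknown:
                    raise ValueError(f"mask for {pop} names unknown treatments {unknown}")
        if sum(self.lineage_partition) != self.n_pop:
            raise ValueError("lineage partition must sum to n_pop")

    @property
    def f_is(self) -> float:
        """Equilibrium inbreeding coefficient under partial selfing."""
        s = self.selfing_rate
        return s / (2.0 - s)

    def population_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pop)]

    def lineage_of(self) -> dict[str, str]:
        out = {}
        pops = self.population_ids()
        k = 0
        for li, size in enumerate(self.lineage_partition):
            for _ in range(size):
                out[pops[k]] = f"L{li + 1}"
                k += 1
        return out

    def provenance(self) -> dict:
        d = asdict(self)
        d["mask"] = None if self.mask is None else "custom"
        return d


def simulate_genotypes(design: SimDesign, seed: int | None = None) -> GenotypeTable:
    """Island-model microsatellite genotypes at the target F_ST.

    Per locus, base allele frequencies are drawn from a flat Dirichlet; each
    population's frequencies from Dirichlet(base * (1 - F) / F), whose
    expected Wright F_ST equals the target.  With F = 0 all populations
    share the base frequencies.  Genotypes are drawn with probability
    ``F_IS`` of copying a single allele (autozygous) and otherwise two
    independent draws; selfing rate 1 therefore yields fully homozygous
    individuals.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pops = design.population_ids()
    n_per = design.n_ind_genotyped
    f = design.target_fst
    f_is = design.f_is
    # distinct code blocks per locus keep alleles locus-specific (fragment bins)
    alleles = np.zeros((design.n_pop * n_per, design.n_loci, 2), dtype=np.int64)
    for j in range(design.n_loci):
        base = rng.dirichlet(np.ones(design.n_alleles))
        codes = 100 + 20 * j + 2 * np.arange(design.n_alleles)
        for i in range(design.n_pop):
            if f == 0.0:
                freqs = base
            else:
                conc = np.maximum(base * (1.0 - f) / f, 1e-9)
                freqs = rng.dirichlet(conc)
            rows = slice(i * n_per, (i + 1) * n_per)
            first = rng.choice(design.n_alleles, size=n_per, p=freqs)
            second = rng.choice(design.n_alleles, size=n_per, p=freqs)
            ibd = rng.random(n_per) < f_is
            second = np.where(ibd, first, second)
            alleles[rows, j, 0] = codes[first]
            alleles[rows, j, 1] = codes[second]
    individuals = [f"{p}_i{k + 1}" for p in pops for k in range(n_per)]
    populations = [p for p in pops for _ in range(n_per)]
    table = GenotypeTable(individuals, populations, [f"L{j + 1:02d}" for j in range(design.n_loci)], alleles)
    return table


def neutral_v_ap(fst: float, v_wp: float) -> float:
    """Among-population variance expected under drift: F_ST 2 V_WP / (1 - F_ST)."""
    if fst >= 1:
        raise ValueError("F_ST must be < 1")
    return fst * 2.0 * v_wp / (1.0 - fst)


def _design_cells(design: SimDesign) -> list[tuple[str, str, int, int]]:
    """(population, treatment, n_families, offspring per family) cells."""
    cells = []
    for pop in design.population_ids():
        for t in design.treatments:
            if design.mask is not None:
                entry = design.mask.get(pop, {})
                if t not in entry:
                    continue
                n_fam, n_ind = entry[t]
            else:
                n_fam = design.families_per_population
                n_ind = n_fam * design.offspring_per_family
            cells.append((pop, t, n_fam, n_ind))
    return cells


def simulate_phenotypes(
    design: SimDesign,
    neutral: bool = False,
    pc1: pd.Series | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format trait table from the nested common-garden model.

    y = mu + treatment effect + population N(0, V_AP) + family N(0, V_WP)
      + family x treatment N(0, V_ft) + residual N(0, V_res),
    plus ``pc1_slope * pc1[population]`` when scores are supplied.
    ``neutral=True`` replaces V_AP with the drift expectation
    F_ST 2 V_WP / (1 - F_ST) at the design's target F_ST.  The optional
    mask reproduces unbalanced designs (cells absent, unequal offspring).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    v_ap = neutral_v_ap(design.target_fst, design.v_wp) if neutral else design.v_ap
    lineage_of = design.lineage_of()
    t_eff = dict(zip(design.treatments, design.treatment_effects))
    pop_eff = {p: rng.normal(0.0, np.sqrt(v_ap)) for p in design.population_ids()}
    fam_eff: dict[str, float] = {}
    ft_eff: dict[tuple[str, str], float] = {}
    rows = []
    for pop, t, n_fam, n_ind in _design_cells(design):
        base = n_ind // n_fam
        extra = n_ind % n_fam
        for fi in range(n_fam):
            fam = f"{pop}_f{fi + 1}"
            if fam not in fam_eff:
                fam_eff[fam] = rng.normal(0.0, np.sqrt(design.v_wp))
            if (fam, t) not in ft_eff:
                ft_eff[(fam, t)] = rng.normal(0.0, np.sqrt(design.v_ft))
            n_off = base + (1 if fi < extra else 0)
            for oi in range(n_off):
                y = (
                    design.grand_mean
                    + t_eff[t]
                    + pop_eff[pop]
                    + fam_eff[fam]
                    + ft_eff[(fam, t)]
                    + rng.normal(0.0, np.sqrt(design.v_res))
                )
                if pc1 is not None:
                    y += design.pc1_slope * float(pc1[pop])
                rows.append({
                    "individual_id": f"{fam}_{t}_o{oi + 1}",
                    "population_id": pop,
                    "seed_family_id": fam,
                    "treatment": t,
                    "lineage": lineage_of[pop],
                    design.trait_name: y,
                })
    df = pd.DataFrame(rows)
    df.attrs["params"] = design.provenance() | {
        "neutral": neutral, "realized_v_ap": v_ap,
        "seed": design.seed if seed is None else seed,
    }
    return df


def simulate_soil(design: SimDesign, seed: int | None = None):
    """Correlated soil variables along a latent gradient, plus coordinates.

    Each of the 11 variables loads on one latent gradient with weight
    ``gradient_weight`` (0 gives an uncorrelated, flat eigenvalue spectrum;
    large values make PC1 dominate) plus unit independent noise.
    Coordinates are uniform over a bounded central-European window.
    Returns ``(soil_df, coords_df)`` indexed/keyed by population id.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pops = design.population_ids()
    g = rng.normal(size=design.n_pop)
    loadings = rng.choice([-1.0, 1.0], size=len(SOIL_VARIABLES))
    data = {}
    for v, load in zip(SOIL_VARIABLES, loadings):
        data[v] = design.gradient_weight * load * g + rng.normal(size=design.n_pop)
    soil = pd.DataFrame(data, index=pops)
    soil.index.name = "population_id"
    coords = pd.DataFrame({
        "population_id": pops,
        "latitude": rng.uniform(50.6, 52.7, design.n_pop),
        "longitude": rng.uniform(10.6, 13.1, design.n_pop),
    })
    return soil, coords


def make_fixture(paper_like: bool = True, seed: int = 0) -> dict:
    """Deterministic bundled dataset for tests and documentation.

    With ``paper_like=True`` the bundled study design supplies population
    ids, coordinates, Q-vectors, gene diversities and the unbalanced
    family/offspring counts per treatment; genotypes, phenotypes and soil
    are simulated around that design at the study-level conditions
    (F_ST 0.66, predominant selfing).  Returns a dict with keys ``design``,
    ``genotypes``, ``traits``, ``q_matrix``, ``soil``, ``coordinates``.
    """
    if not paper_like:
        design = SimDesign(seed=seed)
        soil, coords = simulate_soil(design)
        return {
            "design": None,
            "genotypes": simulate_genotypes(design),
            "traits": simulate_phenotypes(design),
            "q_matrix": None,
            "soil": soil,
            "coordinates": coords,
        }
    sd = study_design()
    mask = {}
    for _, row in sd.iterrows():
        entry = {}
        for t, fam_col, n_col in (("T0", "fam_t0", "n_t0"),
                                  ("T70", "fam_t70", "n_t70"),
                                  ("T150", "fam_t150", "n_t150")):
            if row[fam_col] > 0:
                entry[t] = (int(row[fam_col]), int(row[n_col]))
        mask[row["population_id"]] = entry
    # lineage sizes from the Q-vectors (argmax per population)
    q = sd[["q_eff1", "q_eff2", "q_eff3"]].to_numpy()
    lineage_idx = q.argmax(axis=1)
    partition = tuple(int((lineage_idx == k).sum()) for k in range(3))
    design = SimDesign(n_pop=len(sd), lineage_partition=partition, seed=seed)

    # remap generic ids to the study's population ids, ordered by lineage so
    # the partition labels line up with the Q-vector assignment
    order = np.argsort(lineage_idx, kind="stable")
    pop_map = dict(zip(design.population_ids(), sd["population_id"].to_numpy()[order]))

    genotypes = simulate_genotypes(design)
    genotypes = GenotypeTable(
        [pop_map[p] + ind[ind.index("_"):] for p, ind in
         zip(genotypes.populations, genotypes.individuals)],
        [pop_map[p] for p in genotypes.populations],
        genotypes.loci,
        genotypes.alleles,
    )
    lineage_name = {0: "Eff1", 1: "Eff2", 2: "Eff3"}
    lineage_by_pop = {
        sd["population_id"].iloc[i]: lineage_name[lineage_idx[i]] for i in range(len(sd))
    }
    # phenotypes generated on generic ids under the study's unbalance mask,
    # then renamed to study ids
    traits = simulate_phenotypes(
        SimDesign(n_pop=len(sd), lineage_partition=partition,
                  mask={p: mask[pop_map[p]] for p in design.population_ids()},
                  seed=seed)
    )
    for col in ("individual_id", "seed_family_id"):
        traits[col] = [
            pop_map[v.split("_", 1)[0]] + "_" + v.split("_", 1)[1] for v in traits[col]
        ]
    traits["population_id"] = traits["population_id"].map(pop_map)
    traits["lineage"] = traits["population_id"].map(lineage_by_pop)

    q_matrix = sd[["population_id", "q_eff1", "q_eff2", "q_eff3"]].rename(
        columns={"q_eff1": "Eff1", "q_eff2": "Eff2", "q_eff3": "Eff3"}
    )
    soil, _ = simulate_soil(design)
    soil.index = [pop_map[p] for p in soil.index]
    soil.index.name = "population_id"
    coords = sd[["population_id", "latitude", "longitude"]]
    return {
        "design": sd,
        "genotypes": genotypes,
        "traits": traits,
        "q_matrix": q_matrix,
        "soil": soil,
        "coordinates": coords,
    }
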