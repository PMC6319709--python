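"""Molecular diversity and differentiation statistics for codominant markers.

Implements unbiased gene diversity (expected heterozygosity), the
Weir–Cockerham theta estimator of F-statistics (with a Nei/G_ST variant),
squared codominant genotypic distances, principal coordinate analysis and
threshold-based lineage assignment from an admixture Q-matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeTable

#: Individuals are assigned to a lineage when their largest Q exceeds this.
DEFAULT_Q_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# Expected heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    """Per-population gene diversity.

    ``per_population`` is mean unbiased gene diversity over loci with data;
    ``per_locus`` holds the per-locus values (NaN where a locus is missing in
    all individuals of a population); ``sample_sizes`` the per-locus counts
    of genotyped individuals.
    """

    per_population: pd.Series
    per_locus: pd.DataFrame = field(repr=False)
    sample_sizes: pd.DataFrame = field(repr=False)


def _allele_counts(table: GenotypeTable):
    """Per population, per locus: dict allele -> count, plus diploid n."""
    pops = table.population_ids
    pop_idx = {p: np.array([q == p for q in table.populations]) for p in pops}
    return pops, pop_idx


def expected_heterozygosity(table: GenotypeTable) -> DiversityResult:
    """Unbiased gene diversity per population.

    Per locus: (2n / (2n - 1)) * (1 - sum p_u^2) with n genotyped diploids;
    the population value is the mean over loci with at least one genotyped
    individual.  Monomorphic populations give He = 0.
    """
    pops, pop_idx = _allele_counts(table)
    he = np.full((len(pops), table.n_loci), np.nan)
    ns = np.zeros((len(pops), table.n_loci), dtype=int)
    for i, p in enumerate(pops):
        sub = table.alleles[pop_idx[p]]  # (n_ind_p, n_loci, 2)
        for j in range(table.n_loci):
            a = sub[:, j, :].ravel()
            a = a[a != MISSING]
            n = len(a) // 2
            ns[i, j] = n
            if n == 0:
                continue
            _, counts = np.unique(a, return_counts=True)
            p2 = np.sum((counts / (2 * n)) ** 2)
            he[i, j] = (2 * n / (2 * n - 1)) * (1.0 - p2) if n > 0 else np.nan
    per_locus = pd.DataFrame(he, index=pops, columns=table.loci)
    per_pop = per_locus.mean(axis=1, skipna=True)
    empty = per_pop.isna()
    if empty.any():
        warnings.warn(f"populations with no genotyped loci: {list(per_pop[empty].index)}")
    return DiversityResult(per_pop, per_locus, pd.DataFrame(ns, index=pops, columns=table.loci))


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------

@dataclass
class FstEstimate:
    """Multilocus differentiation estimate.

    ``value`` is the ratio of summed variance components over loci (never a
    mean of per-locus ratios).  Small negative estimates are reported as
    computed.  ``per_locus`` carries the per-locus ratios for the SD that is
    conventionally reported alongside the global estimate.
    """

    scope: str
    estimator: str
    value: float
    per_locus: pd.Series = field(repr=False)

    @property
    def per_locus_sd(self) -> float:
        vals = self.per_locus.dropna()
        return float(vals.std(ddof=1)) if len(vals) > 1 else np.nan


def _wc_components_locus(geno: np.ndarray, groups: np.ndarray):
    """Weir–Cockerham variance components (a, b, c summed over alleles).

    ``geno`` is (n_ind, 2) allele codes for one locus, ``groups`` integer
    group labels.  Returns (a, b, c) or None when fewer than two groups have
    at least two genotyped individuals or the locus is monomorphic.
    """
    ok = (geno != MISSING).all(axis=1)
    geno, groups = geno[ok], groups[ok]
    glabels = np.unique(groups)
    n_i, p_iu, h_iu = [], [], []
    alleles = np.unique(geno)
    if len(alleles) < 2:
        return None
    for g in glabels:
        sub = geno[groups == g]
        n = len(sub)
        if n < 2:
            continue
        n_i.append(n)
        p_iu.append([(sub == u).sum() / (2 * n) for u in alleles])
        h_iu.append([((sub == u).sum(axis=1) == 1).mean() for u in alleles])
    r = len(n_i)
    if r < 2:
        return None
    n_i = np.asarray(n_i, dtype=float)
    p_iu = np.asarray(p_iu)  # (r, n_alleles)
    h_iu = np.asarray(h_iu)
    nsum = n_i.sum()
    nbar = nsum / r
    nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)
    pbar = (n_i[:, None] * p_iu).sum(axis=0) / nsum
    s2 = (n_i[:, None] * (p_iu - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_iu).sum(axis=0) / nsum
    if nbar <= 1 or nc <= 0:
        return None
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def _nei_gst_locus(geno: np.ndarray, groups: np.ndarray):
    """Nei's G_ST components (H_T - H_S, H_T) for one locus."""
    ok = (geno != MISSING).all(axis=1)
    geno, groups = geno[ok], groups[ok]
    glabels = np.unique(groups)
    alleles = np.unique(geno)
    if len(alleles) < 2 or len(glabels) < 2:
        return None
    freqs = []
    for g in glabels:
        sub = geno[groups == g]
        if len(sub) < 1:
            continue
        freqs.append([(sub == u).mean() for u in alleles])
    freqs = np.asarray(freqs)
    hs = np.mean(1.0 - (freqs**2).sum(axis=1))
    pbar = freqs.mean(axis=0)
    ht = 1.0 - (pbar**2).sum()
    if ht <= 0:
        return None
    return ht - hs, ht


def _resolve_groups(table: GenotypeTable, grouping) -> np.ndarray:
    """Map the ``grouping`` argument to one label per individual."""
    if grouping is None or (isinstance(grouping, str) and grouping == "populations"):
        labels = table.populations
    elif isinstance(grouping, dict):  # population -> group
        labels = [grouping[p] for p in table.populations]
    else:
        labels = list(grouping)
        if len(labels) != table.n_individuals:
            raise ValueError("per-individual grouping has wrong length")
    return np.asarray(labels)


def fst(
    table: GenotypeTable,
    grouping="populations",
    estimator: str = "wc",
    scope: str = "populations",
) -> FstEstimate:
    """Multilocus F_ST among groups of individuals.

    Parameters
    ----------
    grouping : "populations", dict, or sequence
        ``"populations"`` uses the table's population labels.  A dict maps
        population id to a coarser group (e.g. lineage) — individuals are
        then pooled per group, the default treatment for between-lineage
        differentiation.  A sequence gives one group label per individual.
    estimator : {"wc", "nei"}
        ``"wc"`` is Weir–Cockerham theta (ratio of summed a over summed
        a+b+c across loci and alleles); ``"nei"`` the G_ST variant.

    Loci monomorphic across the compared groups are dropped (they carry no
    information); negative per-locus components stay in the ratio of sums.
    """
    groups = _resolve_groups(table, grouping)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for differentiation")
    num, den = 0.0, 0.0
    per_locus = {}
    n_poly = 0
    for j, locus in enumerate(table.loci):
        if estimator == "wc":
            comp = _wc_components_locus(table.alleles[:, j, :], groups)
            if comp is None:
                continue
            a, b, c = comp
            num += a
            den += a + b + c
            per_locus[locus] = a / (a + b + c) if (a + b + c) != 0 else np.nan
        elif estimator == "nei":
            comp = _nei_gst_locus(table.alleles[:, j, :], groups)
            if comp is None:
                continue
            dst, ht = comp
            num += dst
            den += ht
            per_locus[locus] = dst / ht
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        n_poly += 1
    if n_poly < 2:
        raise ValueError("fewer than 2 polymorphic loci across the compared groups")
    return FstEstimate(
        scope=scope,
        estimator="theta" if estimator == "wc" else "gst",
        value=num / den,
        per_locus=pd.Series(per_locus),
    )


def pairwise_fst(table: GenotypeTable, estimator: str = "wc") -> pd.DataFrame:
    """Symmetric population x population F_ST matrix (zero diagonal)."""
    pops = table.population_ids
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            sub = table.subset(populations=[p, q])
            try:
                val = fst(sub, estimator=estimator, scope=f"{p}-{q}").value
            except ValueError:
                val = np.nan
            out.loc[p, q] = out.loc[q, p] = val
    return out


def hierarchical_fst(table: GenotypeTable, group_of_pop: dict) -> dict:
    """AMOVA-style hierarchical differentiation: groups / populations / alleles.

    Treats allele copies as the sampling unit in a nested analysis of
    molecular variance and returns the among-group (Phi_CT), among-population-
    within-group (Phi_SC) and total among-population (Phi_ST) fixation
    indices from the method-of-moments variance components, summed over loci.
    Provided as the hierarchical alternative to pooling individuals per group.
    """
    groups = np.asarray([group_of_pop[p] for p in table.populations])
    pops = np.asarray(table.populations)
    sig_a = sig_b = sig_w = 0.0
    for j in range(table.n_loci):
        geno = table.alleles[:, j, :]
        ok = (geno != MISSING).all(axis=1)
        if ok.sum() < 2:
            continue
        g, pp, al = groups[ok], pops[ok], geno[ok]
        alleles = np.unique(al)
        if len(alleles) < 2:
            continue
        # one-hot allele indicators, 2 copies per individual
        x = np.concatenate([al[:, 0:1] == alleles, al[:, 1:2] == alleles], axis=0).astype(float)
        gg = np.concatenate([g, g])
        ppp = np.concatenate([pp, pp])
        N = len(gg)
        grand = x.mean(axis=0)
        ss_total = ((x - grand) ** 2).sum()
        ss_wp, ss_ap_wg, ss_ag = 0.0, 0.0, 0.0
        n_pg, n_g = [], []
        for glab in np.unique(gg):
            sel = gg == glab
            xg = x[sel]
            gmean = xg.mean(axis=0)
            n_g.append(sel.sum())
            ss_ag += sel.sum() * ((gmean - grand) ** 2).sum()
            for plab in np.unique(ppp[sel]):
                psel = sel & (ppp == plab)
                xp = x[psel]
                pmean = xp.mean(axis=0)
                n_pg.append(psel.sum())
                ss_ap_wg += psel.sum() * ((pmean - gmean) ** 2).sum()
                ss_wp += ((xp - pmean) ** 2).sum()
        n_pg = np.asarray(n_pg, dtype=float)
        n_g = np.asarray(n_g, dtype=float)
        npops = len(n_pg)
        ngroups = len(n_g)
        if npops <= ngroups or ngroups < 2:
            continue
        # standard AMOVA coefficients for unbalanced nested designs:
        # sum over groups of (sum n_pg^2 within group)/n_g
        sq_within = 0.0
        for glab, ng in zip(np.unique(gg), n_g):
            sel = gg == glab
            sizes = np.asarray([ (sel & (ppp == plab)).sum() for plab in np.unique(ppp[sel]) ], dtype=float)
            sq_within += (sizes**2).sum() / ng
        n1 = (sq_within - (n_pg**2).sum() / N) / (ngroups - 1)
        n2 = (N - sq_within) / (npops - ngroups)
        n3 = (N - (n_g**2).sum() / N) / (ngroups - 1)
        ms_w = ss_wp / (N - npops)
        ms_p = ss_ap_wg / (npops - ngroups)
        ms_g = ss_ag / (ngroups - 1)
        s2_w = ms_w
        s2_p = (ms_p - s2_w) / n2
        s2_g = (ms_g - s2_w - n1 * s2_p) / n3
        sig_w += s2_w
        sig_b += s2_p
        sig_a += s2_g
    tot = sig_a + sig_b + sig_w
    return {
        "phi_ct": sig_a / tot,
        "phi_sc": sig_b / (sig_b + sig_w),
        "phi_st": (sig_a + sig_b) / tot,
        "components": {"among_groups": sig_a, "among_pops_within": sig_b, "within_pops": sig_w},
    }


# ---------------------------------------------------------------------------
# Genotypic distance and PCoA
# ---------------------------------------------------------------------------

def genotypic_distance(table: GenotypeTable) -> pd.DataFrame:
    """Squared codominant genotypic distance between individuals.

    Per locus the squared distance is half the squared Euclidean distance
    between allele-count vectors, which reproduces the standard codominant
    scheme: 0 identical, 1 one allele substituted, 2 (ij vs kl),
    3 (ii vs jk), 4 (ii vs jj).  Locus values are summed over loci genotyped
    in both individuals; a pair sharing no genotyped locus gets NaN.
    """
    n = table.n_individuals
    total = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for j in range(table.n_loci):
        geno = table.alleles[:, j, :]
        ok = (geno != MISSING).all(axis=1)
        alleles = np.unique(geno[ok])
        if len(alleles) == 0:
            continue
        counts = np.zeros((n, len(alleles)))
        for u, al in enumerate(alleles):
            counts[:, u] = (geno == al).sum(axis=1)
        d2 = 0.5 * (
            (counts**2).sum(axis=1)[:, None]
            + (counts**2).sum(axis=1)[None, :]
            - 2 * counts @ counts.T
        )
        okmat = np.outer(ok, ok)
        total += np.where(okmat, d2, 0.0)
        shared += okmat
    if (shared == 0).any():
        warnings.warn("some individual pairs share no genotyped loci; distances set to NaN")
    out = np.where(shared > 0, total, np.nan)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.individuals, columns=table.individuals)


@dataclass
class PCoAResult:
    """Principal-coordinate ordination of a distance matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def plot(self, ax=None, labels=None, **kwargs):
        """Scatter of the first two axes (diagnostic figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.coordinates.iloc[:, :2].to_numpy()
        if labels is not None:
            for lab in pd.unique(labels):
                sel = np.asarray(labels) == lab
                ax.scatter(xy[sel, 0], xy[sel, 1], label=str(lab), **kwargs)
            ax.legend()
        else:
            ax.scatter(xy[:, 0], xy[:, 1], **kwargs)
        ax.set_xlabel(f"Axis 1 ({self.proportion_explained[0]:.1f}%)")
        ax.set_ylabel(f"Axis 2 ({self.proportion_explained[1]:.1f}%)")
        return ax


def pcoa(distance: pd.DataFrame | np.ndarray, squared: bool = False) -> PCoAResult:
    """Metric multidimensional scaling by Gower double-centering.

    ``squared=True`` declares that the input already holds squared
    distances (as :func:`genotypic_distance` produces).  Negative
    eigenvalues are reported, not dropped; axis percentages are relative to
    the positive eigenvalue mass.
    """
    if isinstance(distance, pd.DataFrame):
        ids = list(distance.index)
        d = distance.to_numpy(dtype=float)
    else:
        d = np.asarray(distance, dtype=float)
        ids = list(range(d.shape[0]))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    d2 = d if squared else d**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    coords = np.zeros_like(evecs)
    coords[:, pos] = evecs[:, pos] * np.sqrt(evals[pos])
    pos_mass = evals[pos].sum()
    prop = np.where(pos, evals / pos_mass * 100.0, 0.0) if pos_mass > 0 else np.zeros_like(evals)
    cols = [f"axis_{k + 1}" for k in range(n)]
    return PCoAResult(pd.DataFrame(coords, index=ids, columns=cols), evals, prop)


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

def assign_lineages(
    q_table: pd.DataFrame,
    threshold: float = DEFAULT_Q_THRESHOLD,
    cluster_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Assign individuals (or populations) to lineages from a Q-matrix.

    Each row's Q-vector must sum to 1 within 0.05 (rounded published tables
    are tolerated).  A row is assigned to the cluster with the largest Q
    when that Q exceeds ``threshold``, otherwise labelled ``"admixed"``.
    If a ``population_id`` column is present, population-level assignments
    from the population mean Q-vector are appended as a second frame
    attribute ``.attrs["population_assignments"]``.
    """
    df = q_table.copy()
    if cluster_columns is None:
        cluster_columns = [
            c for c in df.columns
            if c not in ("individual_id", "population_id") and pd.api.types.is_numeric_dtype(df[c])
        ]
    q = df[cluster_columns].to_numpy(dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("Q values must lie in [0, 1]")
    sums = q.sum(axis=1)
    if ((sums < 0.95) | (sums > 1.05)).any():
        bad = np.flatnonzero((sums < 0.95) | (sums > 1.05))
        raise ValueError(f"Q-vectors not summing to ~1 at rows {bad.tolist()}")
    best = q.argmax(axis=1)
    assigned = [
        cluster_columns[b] if q[i, b] > threshold else "admixed"
        for i, b in enumerate(best)
    ]
    df["lineage"] = assigned
    if "population_id" in df.columns:
        pop_q = df.groupby("population_id")[cluster_columns].mean()
        pbest = pop_q.to_numpy().argmax(axis=1)
        pop_assign = pd.DataFrame(
            {
                "lineage": [
                    cluster_columns[b] if pop_q.iloc[i, b] > threshold else "admixed"
                    for i, b in enumerate(pbest)
                ]
            },
            index=pop_q.index,
        )
        df.attrs["population_assignments"] = pop_assign
    return df
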