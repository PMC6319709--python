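"""Trait-environment association: soil PCA, cline models, He-environment
correlation, pairwise differentiation matrices and multiple matrix
regression with randomization (MMRR).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantgen import ModelSpec, NestedVarianceModel, qst_from_components

DEFAULT_N_PERM = 9999


# ---------------------------------------------------------------------------
# Soil PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of the standardized soil table.

    ``loadings`` are eigenvectors of the correlation matrix (variables x
    axes), ``scores`` the population coordinates, ``pct_variance`` the
    percentage of total variance per axis (summing to 100).
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    pct_variance: np.ndarray

    def plot(self, ax=None):
        """Biplot-style diagnostic of the first two axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.scores.iloc[:, 0], self.scores.iloc[:, 1])
        for var in self.loadings.index:
            lx, ly = self.loadings.loc[var].iloc[:2] * 2.0
            ax.annotate(var, (lx, ly), color="grey")
            ax.arrow(0, 0, lx, ly, color="grey", alpha=0.5)
        ax.set_xlabel(f"PC1 ({self.pct_variance[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({self.pct_variance[1]:.0f}%)")
        return ax


def standardize(df: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Z-score each column (mean 0, SD 1, sample SD); constant columns are
    dropped with a warning since they cannot be standardized."""
    out = {}
    for c in df.columns:
        sd = df[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            if drop_constant:
                warnings.warn(f"dropping constant column {c!r} (SD = 0)")
                continue
            raise ValueError(f"column {c!r} has zero variance")
        out[c] = (df[c] - df[c].mean()) / sd
    return pd.DataFrame(out, index=df.index)


def soil_pca(soil: pd.DataFrame) -> PCAResult:
    """PCA of standardized soil variables (correlation-matrix eigenvectors).

    Rows with any missing value are dropped (listwise deletion).  Axis signs
    are fixed so each axis's largest-magnitude loading is positive.
    """
    df = soil.select_dtypes("number").dropna(axis=0, how="any")
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need >= 3 complete populations and >= 2 soil variables")
    z = standardize(df)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    for k in range(evecs.shape[1]):  # deterministic sign convention
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    axes = [f"PC{k + 1}" for k in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=z.columns, columns=axes)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=df.index, columns=axes)
    pct = evals / evals.sum() * 100.0
    return PCAResult(loadings, scores, pct)


# ---------------------------------------------------------------------------
# Cline models and He correlation
# ---------------------------------------------------------------------------

def trait_env_model(
    trait_table: pd.DataFrame,
    trait: str,
    pc_scores: pd.Series,
    variant: str = "overall",
    treatment: str | None = None,
    seed_mass: pd.Series | None = None,
):
    """Mixed-model cline of a trait on a soil PC axis.

    ``variant="overall"``: PC score and treatment fixed; lineage, population
    and seed family random.  ``variant="per-treatment"``: subset to one
    treatment; PC score, lineage and their interaction fixed; population and
    family random.  ``pc_scores`` (and optional ``seed_mass``) are indexed
    by population id.  Returns ``(results, slope_table)`` where the slope
    table holds Wald z tests for the PC terms.
    """
    df = trait_table.copy()
    df["pc"] = df["population_id"].map(pc_scores)
    if df["pc"].isna().any():
        missing = sorted(df.loc[df["pc"].isna(), "population_id"].unique())
        raise ValueError(f"no PC score for populations {missing}")
    fixed: tuple[str, ...]
    if variant == "overall":
        fixed = ("pc", "treatment")
        random = ("lineage", "population", "family")
    elif variant == "per-treatment":
        if treatment is None:
            raise ValueError("per-treatment variant needs a treatment")
        df = df[df["treatment"] == treatment]
        fixed = ("pc", "lineage", "pc:lineage")
        random = ("population", "family")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if seed_mass is not None:
        df["seed_mass"] = df["population_id"].map(seed_mass)
        fixed = fixed + ("seed_mass",)
    model = NestedVarianceModel.from_dataframe(
        df, ModelSpec(trait, fixed=fixed, random=random)
    )
    res = model.fit_reml()
    wald = res.wald_tests()
    slope_rows = wald.loc[[n for n in wald.index if n.startswith("pc")]]
    return res, slope_rows


def he_env_correlation(he: pd.Series, pc_scores: pd.Series):
    """Pearson correlation between population gene diversity and a PC axis.

    Vectors are aligned on their (population) index.  Returns ``(r, p)``
    from the two-sided t test.
    """
    joined = pd.concat({"he": he, "pc": pc_scores}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired populations")
    if joined["he"].std() == 0 or joined["pc"].std() == 0:
        raise ValueError("zero variance in He or PC scores; correlation undefined")
    r, p = stats.pearsonr(joined["he"], joined["pc"])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

def environmental_distance(soil: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between populations over standardized soil
    variables.  Missing values are handled pairwise-complete (a variable
    missing in either population is skipped for that pair) with a warning."""
    z = standardize(soil.select_dtypes("number"))
    x = z.to_numpy()
    n = len(z)
    if np.isnan(x).any():
        warnings.warn("missing soil values: distances use pairwise-complete variables")
    out = np.zeros((n, n))
    for i in range(n):
        d = x - x[i]
        out[i] = np.sqrt(np.nansum(d**2, axis=1))
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0
    return pd.DataFrame(out, index=z.index, columns=z.index)


def pairwise_qst(
    trait_table: pd.DataFrame,
    trait: str,
    min_families: int = 2,
) -> pd.DataFrame:
    """Population x population trait differentiation matrix (Q^ij_ST).

    For each pair, a two-population nested model (population and seed family
    random; treatment fixed when both treatments occur) is fitted by REML
    and Q^ij_ST = V_AP / (V_AP + 2 V_WP) computed from the components,
    flooring negative estimates at zero.  Pairs that cannot be fitted get a
    missing entry with a warning.
    """
    pops = list(pd.unique(trait_table["population_id"]))
    fams = trait_table.groupby("population_id")["seed_family_id"].nunique()
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in itertools.combinations(pops, 2):
        if fams.get(p1, 0) < min_families or fams.get(p2, 0) < min_families:
            out.loc[p1, p2] = out.loc[p2, p1] = np.nan
            continue
        sub = trait_table[trait_table["population_id"].isin([p1, p2])]
        fixed = ("treatment",) if sub["treatment"].nunique() > 1 else ()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NestedVarianceModel.from_dataframe(
                    sub, ModelSpec(trait, fixed=fixed, random=("population", "family"))
                )
                res = model.fit_reml()
            v_ap = max(res.v_ap, 0.0)
            v_wp = max(res.v_wp, 0.0)
            val = qst_from_components(v_ap, v_wp)
        except Exception as exc:
            warnings.warn(f"pair ({p1}, {p2}) failed to fit: {exc}")
            val = np.nan
        out.loc[p1, p2] = out.loc[p2, p1] = val
    return out


# ---------------------------------------------------------------------------
# MMRR
# ---------------------------------------------------------------------------

@dataclass
class MMRRResult:
    """Multiple matrix regression with randomization.

    ``coefficients`` has one row per predictor (plus the intercept) with the
    standardized coefficient, its t statistic and the two-tailed permutation
    p-value p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1).
    """

    coefficients: pd.DataFrame
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n_perm: int
    n_populations: int

    def summary(self) -> str:
        lines = [
            f"MMRR on {self.n_populations} populations "
            f"(R^2 = {self.r_squared:.3f}, F p = {self.f_pvalue:.4g}, "
            f"{self.n_perm} permutations)",
        ]
        for name, row in self.coefficients.iterrows():
            lines.append(
                f"  {name:<20s} b = {row['coefficient']: .3f}  "
                f"t = {row['t']: .2f}  p = {row['p']:.4g}"
            )
        return "\n".join(lines)


def _unfold(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def mmrr(
    dependent: pd.DataFrame,
    predictors: dict[str, pd.DataFrame],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    standardize_matrices: bool = True,
) -> MMRRResult:
    """Regress one distance/differentiation matrix on several others.

    Lower triangles are unfolded; each vector is z-scored (when
    ``standardize_matrices``) so coefficients are comparable across
    predictors.  Significance comes from simultaneously permuting rows and
    columns of the dependent matrix (Mantel-style), two-tailed on t; the
    observed statistic is counted in both numerator and denominator.
    """
    names = list(predictors)
    pops = list(dependent.index)
    n = len(pops)
    if n < 4:
        raise ValueError("need at least 4 populations")
    mats = [np.asarray(dependent.loc[pops, pops], dtype=float)]
    for name in names:
        m = predictors[name]
        if list(m.index) != pops or list(m.columns) != pops:
            m = m.loc[pops, pops]
        mats.append(np.asarray(m, dtype=float))

    def _zmat(m):
        v = _unfold(m)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("matrix with zero off-diagonal variance")
        out = (m - v.mean()) / sd
        np.fill_diagonal(out, 0.0)
        return out

    if standardize_matrices:
        mats = [_zmat(m) for m in mats]
    ymat = mats[0]
    Xcols = [np.ones(n * (n - 1) // 2)] + [_unfold(m) for m in mats[1:]]
    X = np.column_stack(Xcols)
    p = X.shape[1]
    m_obs = X.shape[0]
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        for (i1, n1), (i2, n2) in itertools.combinations(enumerate(names), 2):
            c = np.corrcoef(X[:, i1 + 1], X[:, i2 + 1])[0, 1]
            if abs(c) > 1 - 1e-10:
                raise ValueError(f"collinear predictors: {n1!r} and {n2!r}")
        raise ValueError("singular predictor set")
    xtx_inv = np.linalg.inv(xtx)
    A = xtx_inv @ X.T
    d = np.diag(xtx_inv)

    def _fit(y):
        b = A @ y
        resid = y - X @ b
        rss = float(resid @ resid)
        s2 = rss / (m_obs - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            # a perfect fit gives infinite t; permutation counting handles it
            t = np.where(s2 > 0, b / np.sqrt(np.maximum(s2, 1e-300) * d),
                         np.sign(b) * np.inf)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        if p > 1 and r2 < 1.0:
            f = (r2 / (p - 1)) / ((1 - r2) / (m_obs - p))
        else:
            f = np.inf if p > 1 else np.nan
        return b, t, r2, f

    y_obs = _unfold(ymat)
    b_obs, t_obs, r2, f_obs = _fit(y_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(p)
    f_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _unfold(ymat[np.ix_(perm, perm)])
        _, t_p, _, f_p = _fit(yp)
        exceed += np.abs(t_p) >= np.abs(t_obs)
        f_exceed += f_p >= f_obs
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    f_pval = (f_exceed + 1.0) / (n_perm + 1.0)
    coef = pd.DataFrame(
        {"coefficient": b_obs, "t": t_obs, "p": pvals},
        index=["Intercept"] + names,
    )
    return MMRRResult(coef, float(r2), float(f_obs), float(f_pval), n_perm, n)
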