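"""Nested variance components and quantitative-trait differentiation (Q_ST).

The central object is :class:`NestedVarianceModel`, a Gaussian mixed model

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I)

for a common-garden seed-family design: random intercepts for population and
for seed family nested in population (optionally family x treatment), fixed
effects for treatment and lineage.  ``fit(method="gibbs")`` runs a blocked
Gibbs sampler with conjugate normal updates for the location effects and
inverse-gamma updates for the variances; ``fit(method="reml")`` delegates to
statsmodels' ``MixedLM`` for restricted maximum likelihood.

Quantitative-trait differentiation is Q_ST = V_AP / (V_AP + 2 V_WP), the
among-population share of additive variance, where V_WP is the seed-family
(within-population) component.  :class:`QstModel` fits the mode-appropriate
mixed model and maps each retained posterior draw through this ratio,
yielding a posterior distribution of Q_ST with credibility intervals taken
directly from the draws.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ChainConfig",
    "NestedVarianceModel",
    "NestedVarianceResults",
    "QstModel",
    "QstResults",
    "qst_from_components",
    "estimate_qst",
    "fit_lmm_gibbs",
    "fit_lmm_reml",
    "posthoc_contrasts",
]

#: Reference level for the nitrogen-addition treatment factor.
TREATMENT_REF = "T0"

#: A lineage needs at least this many populations for a lineage-specific Q_ST.
MIN_POPS_PER_LINEAGE = 4


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings.

    Defaults (13,000 iterations, 3,000 burn-in, thinning 10) retain exactly
    1000 draws, the conventional posterior sample size for Q_ST work.
    """

    iterations: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    seed: int | None = None

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class Priors:
    """Weakly informative inverse-gamma prior on every variance component."""

    shape: float = 0.001
    scale: float = 0.001


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed`` terms are factor names, numeric covariates, or ``a:b``
    interactions; an intercept is always included.  ``random`` terms name
    grouping structures: ``"population"``, ``"family"`` (always nested in
    population), ``"family:treatment"``, ``"population:treatment"``.
    """

    response: str
    fixed: tuple[str, ...] = ("treatment",)
    random: tuple[str, ...] = ("population", "family")

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        for term in self.random:
            if term not in _RANDOM_BUILDERS:
                raise ValueError(f"unknown random term {term!r}")


_RANDOM_BUILDERS = {
    "lineage": lambda df: df["lineage"].astype(str),
    "population": lambda df: df["population_id"].astype(str),
    "family": lambda df: df["population_id"].astype(str) + "/" + df["seed_family_id"].astype(str),
    "family:treatment": lambda df: (
        df["population_id"].astype(str) + "/" + df["seed_family_id"].astype(str)
        + ":" + df["treatment"].astype(str)
    ),
    "population:treatment": lambda df: (
        df["population_id"].astype(str) + ":" + df["treatment"].astype(str)
    ),
}


def _factor_levels(df: pd.DataFrame, name: str) -> list[str]:
    levels = sorted(map(str, df[name].dropna().unique()))
    ref = TREATMENT_REF if name == "treatment" and TREATMENT_REF in levels else levels[0]
    return [ref] + [l for l in levels if l != ref]


def build_fixed_design(df: pd.DataFrame, terms: tuple[str, ...]):
    """Treatment-contrast design matrix with predictable column names.

    Returns ``(X, names, meta, factor_levels)`` where ``meta[j]`` maps each
    categorical factor appearing in column j to its level, plus numeric
    factor names under the key ``"__numeric__"``.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    meta: list[dict] = [{}]
    factor_levels: dict[str, list[str]] = {}
    for term in terms:
        factors = term.split(":")
        per_factor = []
        for f in factors:
            if pd.api.types.is_numeric_dtype(df[f]):
                per_factor.append([("__numeric__", f, df[f].to_numpy(dtype=float))])
            else:
                levels = factor_levels.setdefault(f, _factor_levels(df, f))
                vals = df[f].astype(str).to_numpy()
                per_factor.append(
                    [(f, lev, (vals == lev).astype(float)) for lev in levels[1:]]
                )
        for combo in itertools.product(*per_factor):
            col = np.ones(n)
            info: dict = {}
            parts = []
            for fac, lev, vec in combo:
                col = col * vec
                if fac == "__numeric__":
                    info.setdefault("__numeric__", []).append(lev)
                    parts.append(lev)
                else:
                    info[fac] = lev
                    parts.append(f"{fac}[{lev}]")
            cols.append(col)
            names.append(":".join(parts))
            meta.append(info)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an aliased column by sequential rank growth
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise ValueError(f"aliased fixed-effect column: {names[j]}")
            r = rj
    return X, names, meta, factor_levels


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class NestedVarianceResults:
    """Fitted nested mixed model (Gibbs posterior or REML point fit).

    ``vcomp`` holds the variance-component point estimates (posterior
    medians for the Gibbs path), ``fe_params`` the fixed effects.  The Gibbs
    path additionally fills ``posterior`` with one row per retained draw;
    variance columns are the random-term names plus ``"residual"``.
    """

    model: "NestedVarianceModel"
    method: str
    fe_params: pd.Series
    vcomp: pd.Series
    posterior: pd.DataFrame | None = field(default=None, repr=False)
    fe_se: pd.Series | None = None
    converged: bool = True
    chain: ChainConfig | None = None
    _sm_result: object | None = field(default=None, repr=False)

    @property
    def v_ap(self) -> float:
        """Among-population variance component."""
        return float(self.vcomp["population"])

    @property
    def v_wp(self) -> float:
        """Within-population (seed-family) variance component."""
        return float(self.vcomp["family"])

    def wald_tests(self) -> pd.DataFrame:
        """Per-coefficient z tests (REML path)."""
        if self.fe_se is None:
            raise ValueError("standard errors only available for the REML fit")
        z = self.fe_params / self.fe_se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.fe_params, "se": self.fe_se, "z": z, "p": p}
        )

    def summary(self) -> str:
        lines = [
            f"Nested variance-component model ({self.method.upper()})",
            f"  response: {self.model.spec.response}   n = {self.model.nobs}",
            "",
            "Fixed effects:",
        ]
        for name, val in self.fe_params.items():
            se = f"  (se {self.fe_se[name]:.4g})" if self.fe_se is not None else ""
            lines.append(f"  {name:<30s} {val: .4g}{se}")
        lines.append("")
        lines.append("Variance components:")
        for name, val in self.vcomp.items():
            if self.posterior is not None and name in self.posterior:
                lo, hi = np.percentile(self.posterior[name], [2.5, 97.5])
                lines.append(f"  {name:<30s} {val: .4g}  [95% CrI {lo:.4g}, {hi:.4g}]")
            else:
                lines.append(f"  {name:<30s} {val: .4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class NestedVarianceModel:
    """Gaussian mixed model for a nested common-garden design.

    Build from a long-format trait table with
    :meth:`from_dataframe`; fit with :meth:`fit`.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, fe_names: list[str],
                 fe_meta: list[dict], factor_levels: dict,
                 random_index: dict[str, np.ndarray],
                 random_levels: dict[str, list[str]],
                 spec: ModelSpec, data: pd.DataFrame):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.fe_names = fe_names
        self.fe_meta = fe_meta
        self.factor_levels = factor_levels
        self.random_index = random_index
        self.random_levels = random_levels
        self.spec = spec
        self.data = data

    nobs = property(lambda self: len(self.y))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "NestedVarianceModel":
        df = data.dropna(subset=[spec.response]).copy()
        if df["population_id"].nunique() < 2:
            raise ValueError("need at least 2 populations")
        fam = _RANDOM_BUILDERS["family"](df)
        pops_with_2fam = df.assign(_f=fam).groupby("population_id")["_f"].nunique()
        if (pops_with_2fam >= 2).sum() < 2:
            raise ValueError("need >= 2 families in >= 2 populations")
        if not np.isfinite(df[spec.response].to_numpy(dtype=float)).all():
            raise ValueError("non-finite response values")
        X, names, meta, flevels = build_fixed_design(df, spec.fixed)
        rindex, rlevels = {}, {}
        for term in spec.random:
            labels = _RANDOM_BUILDERS[term](df)
            codes, levels = pd.factorize(labels)
            rindex[term] = codes
            rlevels[term] = list(levels)
        return cls(df[spec.response].to_numpy(dtype=float), X, names, meta,
                   flevels, rindex, rlevels, spec, df)

    # -- fitting ----------------------------------------------------------

    def fit(self, method: str = "gibbs", **kwargs) -> NestedVarianceResults:
        if method == "gibbs":
            return self.fit_gibbs(**kwargs)
        if method == "reml":
            return self.fit_reml(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_gibbs(
        self,
        chain: ChainConfig | None = None,
        priors: Priors = Priors(),
        seed: int | None = None,
    ) -> NestedVarianceResults:
        """Blocked Gibbs sampler with conjugate updates.

        Location effects (fixed block, then each random term) are drawn from
        their conditional normals; each variance from its conditional
        inverse-gamma.  Draws after burn-in are thinned to the configured
        retained count; the same seed reproduces the chain bit-for-bit.
        """
        chain = chain or ChainConfig()
        if seed is not None:
            chain = replace(chain, seed=seed)
        rng = np.random.default_rng(chain.seed)
        y, X = self.y, self.X
        n, p = X.shape
        terms = list(self.random_index)
        idx = {k: self.random_index[k] for k in terms}
        q = {k: len(self.random_levels[k]) for k in terms}
        counts = {k: np.bincount(idx[k], minlength=q[k]).astype(float) for k in terms}

        xtx = X.T @ X
        xtx_chol = np.linalg.cholesky(xtx)

        beta = np.linalg.solve(xtx, X.T @ y)
        u = {k: np.zeros(q[k]) for k in terms}
        resid_var = max(float(np.var(y - X @ beta)), 1e-8)
        s2 = {k: resid_var / (len(terms) + 1) for k in terms}
        s2e = resid_var

        n_ret = chain.n_retained
        fe_draws = np.empty((n_ret, p))
        var_draws = np.empty((n_ret, len(terms) + 1))
        a0, b0 = priors.shape, priors.scale

        zu_total = np.zeros(n)
        for k in terms:
            zu_total += u[k][idx[k]]

        kept = 0
        for it in range(chain.iterations):
            # fixed effects block
            r = y - zu_total
            mean = np.linalg.solve(xtx, X.T @ r)
            z = rng.standard_normal(p)
            beta = mean + np.sqrt(s2e) * np.linalg.solve(xtx_chol.T, z)
            xb = X @ beta
            # random terms, one block each
            for k in terms:
                zu_total -= u[k][idx[k]]
                r = y - xb - zu_total
                ssum = np.bincount(idx[k], weights=r, minlength=q[k])
                prec = counts[k] / s2e + 1.0 / s2[k]
                mu = (ssum / s2e) / prec
                u[k] = mu + rng.standard_normal(q[k]) / np.sqrt(prec)
                zu_total += u[k][idx[k]]
                s2[k] = (b0 + 0.5 * float(u[k] @ u[k])) / rng.gamma(a0 + 0.5 * q[k])
            e = y - xb - zu_total
            s2e = (b0 + 0.5 * float(e @ e)) / rng.gamma(a0 + 0.5 * n)
            if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and kept < n_ret:
                fe_draws[kept] = beta
                var_draws[kept] = [s2[k] for k in terms] + [s2e]
                kept += 1

        var_cols = terms + ["residual"]
        posterior = pd.DataFrame(
            np.column_stack([fe_draws, var_draws]),
            columns=self.fe_names + var_cols,
        )
        fe = posterior[self.fe_names].median()
        vc = posterior[var_cols].median()
        return NestedVarianceResults(
            model=self, method="gibbs", fe_params=fe, vcomp=vc,
            posterior=posterior, chain=chain,
        )

    def fit_reml(self, maxiter: int = 200) -> NestedVarianceResults:
        """REML via statsmodels ``MixedLM``.

        The coarsest random term (lineage when present, else population) is
        the top grouping; the remaining random terms enter as variance
        components nested within it.  Non-convergence raises with the
        optimizer trace attached.
        """
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import VCSpec

        terms = list(self.random_index)
        top = "lineage" if "lineage" in terms else "population"
        if top not in terms:
            raise ValueError("REML path expects a population or lineage random term")
        df = self.data
        groups = _RANDOM_BUILDERS[top](df).to_numpy()
        vc_terms = [t for t in terms if t != top]
        names_vc, colnames_vc, mats_vc = [], [], []
        for t in vc_terms:
            labels = pd.Categorical(
                np.asarray(self.random_levels[t])[self.random_index[t]],
                categories=self.random_levels[t],
            )
            dummies = pd.get_dummies(labels, dtype=float)
            names_vc.append(t)
            cn, ms = [], []
            # MixedLM sorts group labels internally; blocks must match
            for g in sorted(set(groups)):
                sel = groups == g
                sub = dummies.loc[sel]
                keep = sub.columns[(sub != 0).any(axis=0)]
                cn.append(list(keep))
                ms.append(sub[keep].to_numpy())
            colnames_vc.append(cn)
            mats_vc.append(ms)
        exog_vc = VCSpec(names_vc, colnames_vc, mats_vc) if vc_terms else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                self.y, self.X, groups=groups,
                exog_re=np.ones((self.nobs, 1)),
                exog_vc=exog_vc,
            )
            res = None
            last_exc: Exception | None = None
            for opt in ("bfgs", "lbfgs", "powell"):
                try:
                    cand = model.fit(reml=True, maxiter=maxiter, method=opt)
                except Exception as exc:  # singular step, linalg failure
                    last_exc = exc
                    continue
                if cand.converged:
                    res = cand
                    break
                res = res or cand
            if res is None:
                raise RuntimeError(f"REML did not converge: {last_exc}")
        if not res.converged:
            raise RuntimeError(
                f"REML did not converge after {maxiter} iterations; "
                f"final params {np.asarray(res.params)}"
            )
        vc = {top: float(np.asarray(res.cov_re)[0, 0])}
        for i, t in enumerate(vc_terms):
            vc[t] = float(res.vcomp[i])
        vc["residual"] = float(res.scale)
        fe = pd.Series(res.fe_params, index=self.fe_names)
        se = pd.Series(np.asarray(res.bse_fe), index=self.fe_names)
        return NestedVarianceResults(
            model=self, method="reml", fe_params=fe,
            vcomp=pd.Series(vc), fe_se=se, converged=True, _sm_result=res,
        )


def fit_lmm_gibbs(
    spec: ModelSpec,
    data: pd.DataFrame,
    priors: Priors = Priors(),
    chain: ChainConfig | None = None,
    seed: int | None = None,
) -> NestedVarianceResults:
    """Functional wrapper: build the model from ``data`` and run the Gibbs fit."""
    model = NestedVarianceModel.from_dataframe(data, spec)
    return model.fit_gibbs(chain=chain, priors=priors, seed=seed)


def fit_lmm_reml(spec: ModelSpec, data: pd.DataFrame) -> NestedVarianceResults:
    """Functional wrapper: build the model from ``data`` and run the REML fit."""
    model = NestedVarianceModel.from_dataframe(data, spec)
    return model.fit_reml()


# ---------------------------------------------------------------------------
# Q_ST
# ---------------------------------------------------------------------------

def qst_from_components(v_ap, v_wp):
    """Q_ST = V_AP / (V_AP + 2 V_WP); both components must be non-negative.

    Vectorized; returns NaN where both components are zero (undefined).
    """
    v_ap = np.asarray(v_ap, dtype=float)
    v_wp = np.asarray(v_wp, dtype=float)
    if (v_ap < 0).any() or (v_wp < 0).any():
        raise ValueError("variance components must be non-negative")
    den = v_ap + 2.0 * v_wp
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, v_ap / np.where(den > 0, den, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


_MODES = ("across-treatment", "per-treatment", "per-lineage")


def _mode_spec(trait: str, mode: str, include_family_treatment: bool) -> ModelSpec:
    if mode == "per-treatment":
        return ModelSpec(trait, fixed=(), random=("population", "family"))
    random = ("population", "family") + (
        ("family:treatment",) if include_family_treatment else ()
    )
    return ModelSpec(trait, fixed=("treatment",), random=random)


@dataclass
class QstResults:
    """Posterior summary of quantitative-trait differentiation.

    ``draws`` are the retained posterior Q_ST values (one per variance draw),
    every one in [0, 1] by construction; the 95% interval is the equal-tailed
    2.5/97.5 percentile band of the draws.
    """

    trait: str
    mode: str
    subset: str | None
    draws: np.ndarray = field(repr=False)
    v_ap_draws: np.ndarray = field(repr=False)
    v_wp_draws: np.ndarray = field(repr=False)
    fit: NestedVarianceResults = field(repr=False, default=None)

    @property
    def median(self) -> float:
        return float(np.median(self.draws))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.ci
        sub = f" [{self.subset}]" if self.subset else ""
        return (
            f"Q_ST({self.trait}, {self.mode}{sub}) = {self.median:.3f} "
            f"(95% CrI {lo:.3f}-{hi:.3f}, {len(self.draws)} draws)"
        )

    def to_row(self) -> dict:
        lo, hi = self.ci
        return {
            "trait": self.trait, "mode": self.mode, "subset": self.subset,
            "qst_median": self.median, "ci_lo": lo, "ci_hi": hi,
        }


class QstModel:
    """Mixed model for one trait in one Q_ST mode.

    Modes: ``across-treatment`` (treatment fixed; population, family and —
    by default — family x treatment random), ``per-treatment`` (subset to
    one treatment; population and family random), ``per-lineage``
    (across-treatment model on one lineage's populations; lineages with
    fewer than 4 populations are refused).  V_WP is always the seed-family
    component alone.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        mode: str = "across-treatment",
        treatment: str | None = None,
        lineage: str | None = None,
        include_family_treatment: bool = True,
    ):
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        df = data
        if mode == "per-treatment":
            if treatment is None:
                raise ValueError("per-treatment mode needs a treatment")
            df = df[df["treatment"] == treatment]
            if not len(df):
                raise ValueError(f"no observations for treatment {treatment!r}")
        if mode == "per-lineage":
            if lineage is None:
                raise ValueError("per-lineage mode needs a lineage")
            df = df[df["lineage"] == lineage]
            npop = df["population_id"].nunique()
            if npop < 2:
                raise ValueError(f"lineage {lineage!r} has {npop} population(s); need >= 2")
            if npop < MIN_POPS_PER_LINEAGE:
                raise ValueError(
                    f"lineage {lineage!r} has only {npop} populations; "
                    f"lineage-specific Q_ST requires >= {MIN_POPS_PER_LINEAGE}"
                )
        self.trait = trait
        self.mode = mode
        self.subset = treatment if mode == "per-treatment" else lineage
        spec = _mode_spec(trait, mode, include_family_treatment)
        self.inner = NestedVarianceModel.from_dataframe(df, spec)

    def fit(
        self,
        seed: int | None = None,
        chain: ChainConfig | None = None,
        priors: Priors = Priors(),
    ) -> QstResults:
        res = self.inner.fit_gibbs(chain=chain, priors=priors, seed=seed)
        v_ap = res.posterior["population"].to_numpy()
        v_wp = res.posterior["family"].to_numpy()
        draws = qst_from_components(v_ap, v_wp)
        return QstResults(self.trait, self.mode, self.subset,
                          draws, v_ap, v_wp, res)


def estimate_qst(
    data: pd.DataFrame,
    trait: str,
    mode: str = "across-treatment",
    treatment: str | None = None,
    lineage: str | None = None,
    seed: int | None = None,
    chain: ChainConfig | None = None,
    include_family_treatment: bool = True,
):
    """Estimate Q_ST for one trait.

    When ``mode`` needs a subset (treatment or lineage) and none is given,
    fits every admissible level and returns a dict keyed by level (lineages
    below the population minimum are skipped).  Otherwise returns a single
    :class:`QstResults`.
    """
    def _one(t=None, l=None, s=None):
        return QstModel(
            data, trait, mode, treatment=t, lineage=l,
            include_family_treatment=include_family_treatment,
        ).fit(seed=s, chain=chain)

    rng = np.random.default_rng(seed)
    if mode == "per-treatment" and treatment is None:
        out = {}
        for t in sorted(data["treatment"].unique()):
            out[t] = _one(t=t, s=int(rng.integers(2**31 - 1)))
        return out
    if mode == "per-lineage" and lineage is None:
        out = {}
        for l in sorted(data["lineage"].dropna().unique()):
            npop = data.loc[data["lineage"] == l, "population_id"].nunique()
            if npop < MIN_POPS_PER_LINEAGE:
                continue
            out[l] = _one(l=l, s=int(rng.integers(2**31 - 1)))
        return out
    return _one(t=treatment, l=lineage, s=seed)


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

def _marginal_mean_row(results: NestedVarianceResults, factor: str, level: str) -> np.ndarray:
    """Design row for the adjusted (marginal) mean of one factor level.

    Other categorical factors are averaged with equal level weights;
    numeric covariates are held at their sample mean.
    """
    model = results.model
    row = np.zeros(len(model.fe_names))
    for j, info in enumerate(model.fe_meta):
        val = 1.0
        for fac, lev in info.items():
            if fac == "__numeric__":
                for cov in lev:
                    val *= float(model.data[cov].mean())
            elif fac == factor:
                val *= 1.0 if lev == level else 0.0
            else:
                val *= 1.0 / len(model.factor_levels[fac])
        row[j] = val
    return row


def posthoc_contrasts(results: NestedVarianceResults, factor: str) -> pd.DataFrame:
    """All pairwise adjusted-mean differences for one fixed factor.

    REML path: Wald z tests with Holm-adjusted p-values.  Gibbs path:
    posterior median differences with 95% equal-tailed credibility
    intervals.  A single-level factor yields an empty table.
    """
    model = results.model
    if factor not in model.factor_levels:
        raise ValueError(f"{factor!r} is not a categorical fixed factor of this model")
    levels = model.factor_levels[factor]
    if len(levels) < 2:
        return pd.DataFrame(columns=["level_1", "level_2", "difference"])
    rows = []
    for l1, l2 in itertools.combinations(levels, 2):
        c = _marginal_mean_row(results, factor, l2) - _marginal_mean_row(results, factor, l1)
        if results.method == "gibbs":
            diff_draws = results.posterior[model.fe_names].to_numpy() @ c
            lo, hi = np.percentile(diff_draws, [2.5, 97.5])
            rows.append({
                "level_1": l1, "level_2": l2,
                "difference": float(np.median(diff_draws)),
                "ci_lo": float(lo), "ci_hi": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            })
        else:
            sm_res = results._sm_result
            beta = results.fe_params.to_numpy()
            cov = np.asarray(sm_res.cov_params())[: len(beta), : len(beta)]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            z = diff / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z))
            rows.append({
                "level_1": l1, "level_2": l2, "difference": diff,
                "se": se, "z": z, "p": p,
            })
    out = pd.DataFrame(rows)
    if "p" in out.columns:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"], method="holm")[1]
        out["significant"] = out["p_holm"] < 0.05
    return out
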