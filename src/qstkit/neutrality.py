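"""Neutral expectation for quantitative-trait differentiation and the
Q_ST - Q^n_ST difference test.

Under drift alone, the expected among-population additive variance given a
neutral differentiation level F_ST and within-population additive variance
V_A is V_P^n = F_ST * 2 V_A / (1 - F_ST).  Its sampling distribution over a
finite number of demes is emulated by scaling with r / (n_pop - 1), r drawn
from a chi-square with n_pop - 1 degrees of freedom.  Each simulated
variance is mapped to a neutral Q^n_ST using the observed within-population
variance, and the test statistic is the index-paired difference between
posterior Q_ST draws and simulated Q^n_ST draws: a 95% credible interval of
the differences entirely above (below) zero signals directional
(stabilizing) selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantgen import ChainConfig, QstResults, estimate_qst

DEFAULT_N_SIM = 1000


@dataclass
class NeutralSimConfig:
    """Configuration of one neutral Q^n_ST simulation.

    ``v_a`` and ``v_wp_obs`` may be scalars or draw vectors (posterior
    samples); vectors must have length ``n_sim`` so draws pair by index.
    ``v_a_multiplier`` rescales V_A (default 1.0: V_A is taken equal to the
    seed-family variance draws, with no selfing correction).
    """

    fst: float
    n_pop: int
    n_sim: int = DEFAULT_N_SIM
    v_a: float | np.ndarray = 1.0
    v_wp_obs: float | np.ndarray = 1.0
    v_a_multiplier: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.fst >= 1.0:
            raise ValueError("F_ST must be < 1")
        if self.fst < 0.0:
            warnings.warn("negative F_ST clipped to 0 for the neutral simulation")
            self.fst = 0.0
        if self.n_pop < 2:
            raise ValueError("need n_pop >= 2")
        for name in ("v_a", "v_wp_obs"):
            val = getattr(self, name)
            if np.ndim(val) > 0 and len(np.atleast_1d(val)) != self.n_sim:
                raise ValueError(f"{name} vector length must equal n_sim={self.n_sim}")


def simulate_neutral_qst(config: NeutralSimConfig) -> np.ndarray:
    """Draw ``n_sim`` neutral Q^n_ST values.

    For each simulation i: V_P^n(i) = F_ST * (2 V_A(i) / (1 - F_ST)) *
    r_i / (n_pop - 1) with r_i ~ chi2(n_pop - 1), then
    Q^n_ST(i) = V_P^n(i) / (V_P^n(i) + 2 V_WP_obs(i)).
    """
    rng = np.random.default_rng(config.seed)
    v_a = np.broadcast_to(
        np.atleast_1d(np.asarray(config.v_a, dtype=float)), (config.n_sim,)
    ) * config.v_a_multiplier
    v_wp = np.broadcast_to(
        np.atleast_1d(np.asarray(config.v_wp_obs, dtype=float)), (config.n_sim,)
    )
    dof = config.n_pop - 1
    r = rng.chisquare(dof, size=config.n_sim)
    v_np = config.fst * (2.0 * v_a / (1.0 - config.fst)) * r / dof
    den = v_np + 2.0 * v_wp
    with np.errstate(invalid="ignore"):
        q = np.where(den > 0, v_np / np.where(den > 0, den, 1.0), 0.0)
    return q


@dataclass
class QstFstTest:
    """Result of the paired Q_ST - Q^n_ST comparison for one trait/mode.

    ``verdict`` is ``"directional"`` when the 95% equal-tailed credible
    interval of the differences lies entirely above zero, ``"stabilizing"``
    when entirely below, else ``"neutral"``.
    """

    trait: str
    mode: str
    subset: str | None
    differences: np.ndarray = field(repr=False)
    median: float = 0.0
    ci: tuple[float, float] = (0.0, 0.0)
    verdict: str = "neutral"

    def summary(self) -> str:
        sub = f" [{self.subset}]" if self.subset else ""
        return (
            f"Q_ST - Q^n_ST ({self.trait}, {self.mode}{sub}): "
            f"median {self.median:+.3f}, 95% CrI [{self.ci[0]:+.3f}, "
            f"{self.ci[1]:+.3f}] -> {self.verdict}"
        )

    def to_row(self) -> dict:
        return {
            "trait": self.trait, "mode": self.mode, "subset": self.subset,
            "median_diff": self.median, "ci_lo": self.ci[0],
            "ci_hi": self.ci[1], "verdict": self.verdict,
        }


def qst_fst_test(
    qst_draws: np.ndarray,
    qnst_draws: np.ndarray,
    trait: str = "",
    mode: str = "",
    subset: str | None = None,
) -> QstFstTest:
    """Index-paired difference test between posterior and neutral draws."""
    qst_draws = np.asarray(qst_draws, dtype=float)
    qnst_draws = np.asarray(qnst_draws, dtype=float)
    if qst_draws.shape != qnst_draws.shape:
        raise ValueError(
            f"draw vectors differ in length ({len(qst_draws)} vs {len(qnst_draws)})"
        )
    diff = qst_draws - qnst_draws
    lo, hi = np.percentile(diff, [2.5, 97.5])
    if lo > 0:
        verdict = "directional"
    elif hi < 0:
        verdict = "stabilizing"
    else:
        verdict = "neutral"
    return QstFstTest(
        trait=trait, mode=mode, subset=subset, differences=diff,
        median=float(np.median(diff)), ci=(float(lo), float(hi)), verdict=verdict,
    )


def compare_to_neutral(
    qst: QstResults,
    fst_value: float,
    n_pop: int,
    seed: int | None = None,
    v_a_multiplier: float = 1.0,
) -> QstFstTest:
    """Run the full neutral comparison for one fitted Q_ST posterior.

    V_A and the observed V_WP are the posterior seed-family variance draws
    of the fitted model, paired by index with the Q_ST draws.
    """
    cfg = NeutralSimConfig(
        fst=float(fst_value),  # config clips negative estimates to 0
        n_pop=n_pop,
        n_sim=len(qst.draws),
        v_a=qst.v_wp_draws,
        v_wp_obs=qst.v_wp_draws,
        v_a_multiplier=v_a_multiplier,
        seed=seed,
    )
    qnst = simulate_neutral_qst(cfg)
    return qst_fst_test(qst.draws, qnst, qst.trait, qst.mode, qst.subset)


def run_qstfst_suite(
    trait_table: pd.DataFrame,
    fst_values: dict,
    traits: list[str],
    modes: tuple[str, ...] = ("across-treatment",),
    seed: int | None = None,
    chain: ChainConfig | None = None,
) -> pd.DataFrame:
    """One difference test per trait x mode (x subset).

    ``fst_values`` maps a subset key to the F_ST computed on exactly that
    subset's populations: ``"global"`` for across-treatment, the treatment
    label for per-treatment subsets, the lineage label for per-lineage.
    Missing keys raise.  A fixed ``seed`` reproduces the table exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        for mode in modes:
            if mode == "across-treatment":
                fits = {"global": estimate_qst(
                    trait_table, trait, mode, seed=int(rng.integers(2**31 - 1)),
                    chain=chain,
                )}
            else:
                fits = estimate_qst(
                    trait_table, trait, mode, seed=int(rng.integers(2**31 - 1)),
                    chain=chain,
                )
            for key, qres in fits.items():
                if key not in fst_values:
                    raise KeyError(f"no F_ST supplied for subset {key!r}")
                if mode == "per-treatment":
                    sub = trait_table[trait_table["treatment"] == key]
                elif mode == "per-lineage":
                    sub = trait_table[trait_table["lineage"] == key]
                else:
                    sub = trait_table
                n_pop = sub["population_id"].nunique()
                test = compare_to_neutral(
                    qres, fst_values[key], n_pop,
                    seed=int(rng.integers(2**31 - 1)),
                )
                row = test.to_row()
                row.update({"qst_median": qres.median, "fst": fst_values[key],
                            "n_pop": n_pop})
                rows.append(row)
    return pd.DataFrame(rows)


def plot_qst_fst(tests: pd.DataFrame, ax=None):
    """Point-and-interval display of the difference tests (diagnostic)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(tests) + 1))
    y = np.arange(len(tests))
    ax.errorbar(
        tests["median_diff"], y,
        xerr=[tests["median_diff"] - tests["ci_lo"], tests["ci_hi"] - tests["median_diff"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=1)
    labels = tests["trait"] + np.where(
        tests["subset"].notna(), " (" + tests["subset"].astype(str) + ")", ""
    )
    ax.set_yticks(y, labels)
    ax.set_xlabel("Q_ST - Q$^n$_ST (posterior median, 95% CrI)")
    return ax
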