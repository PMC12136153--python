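"""Group-level summaries and inference.

Inhibition prevalences are reported as proportions with binomial standard
errors sqrt(p(1-p)/n).  Group comparisons of binary inhibition status use a
logit-link mixed model with a random intercept per individual butterfly
(Laplace ML, see :mod:`specsense.mixed`); lambda-max comparisons use a
Gaussian linear mixed model with the same random-effect structure
(statsmodels MixedLM).  Per-group lambda-max values are also tested against
the expected tuning of candidate opsins with one-sample t-tests under
Bonferroni correction, and response half-max durations are compared across
photoreceptor types with a one-way ANOVA followed by Tukey's HSD with a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .mixed import MixedModelFit, logistic_mixed_fit

__all__ = [
    "GroupProportion",
    "proportion_with_sem",
    "fit_logistic_mixed",
    "fit_linear_mixed",
    "pairwise_logistic_contrast",
    "ttest_vs_expected",
    "anova_tukey",
    "kde_mode_count",
]


@dataclass(frozen=True)
class GroupProportion:
    group: str
    k: int
    n: int
    p_hat: float
    sem: float
    n_individuals: int | None = None

    @property
    def percent(self) -> float:
        return round(100.0 * self.p_hat, 1)

    @property
    def percent_sem(self) -> float:
        return round(100.0 * self.sem, 1)


def proportion_with_sem(k: int, n: int, group: str = "", n_individuals=None) -> GroupProportion:
    """Observed proportion with its binomial standard error sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    sem = float(np.sqrt(p * (1.0 - p) / n))
    return GroupProportion(group=group, k=int(k), n=int(n), p_hat=float(p), sem=sem,
                           n_individuals=n_individuals)


def _design_from_groups(data: pd.DataFrame, response: str, group_col: str):
    levels = sorted(data[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    X = np.column_stack(
        [np.ones(len(data))]
        + [(data[group_col] == lv).astype(float).to_numpy() for lv in levels[1:]]
    )
    names = ["intercept"] + [f"{group_col}[{lv}]" for lv in levels[1:]]
    return data[response].to_numpy(dtype=float), X, names, levels


def fit_logistic_mixed(
    data: pd.DataFrame,
    response: str = "inhibited",
    group_col: str = "group",
    individual_col: str = "individual_id",
    sigma: float | None = None,
) -> MixedModelFit:
    """Logit-link mixed model: binary outcome ~ group + (1 | individual)."""
    y, X, names, _ = _design_from_groups(data, response, group_col)
    return logistic_mixed_fit(y, X, data[individual_col].to_numpy(), names=names,
                              sigma=sigma)


def pairwise_logistic_contrast(
    data: pd.DataFrame,
    group_a: str,
    group_b: str,
    response: str = "inhibited",
    group_col: str = "group",
    individual_col: str = "individual_id",
) -> dict:
    """Two-group mixed-model contrast; returns estimate, t and p for b vs a."""
    sub = data[data[group_col].isin([group_a, group_b])].copy()
    y = sub[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub)), (sub[group_col] == group_b).astype(float).to_numpy()]
    )
    fit = logistic_mixed_fit(
        y, X, sub[individual_col].to_numpy(), names=("intercept", "contrast")
    )
    return {
        "groups": (group_a, group_b),
        "estimate": float(fit.params[1]),
        "se": float(fit.se[1]),
        "t": float(fit.tstats[1]),
        "p": float(fit.pvalues[1]),
        "random_intercept_sd": fit.random_intercept_sd,
        "converged": fit.converged,
    }


def fit_linear_mixed(
    data: pd.DataFrame,
    response: str = "lambda_max",
    group_col: str = "group",
    individual_col: str = "individual_id",
) -> MixedModelFit:
    """Gaussian mixed model: response ~ group + (1 | individual), REML off."""
    import warnings as _warnings

    y, X, names, _ = _design_from_groups(data, response, group_col)
    k = X.shape[1]
    try:
        model = sm.MixedLM(y, X, groups=data[individual_col].to_numpy())
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        params = np.asarray(res.fe_params)
        se = np.asarray(res.bse[:k])
        sd = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        llf, conv = float(res.llf), bool(res.converged)
    except np.linalg.LinAlgError:
        # variance at the boundary (sigma -> 0): the model degenerates to OLS
        ols = sm.OLS(y, X).fit()
        params = np.asarray(ols.params)
        se = np.asarray(ols.bse)
        sd, llf, conv = 0.0, float(ols.llf), True
    t = params / se
    p = 2.0 * sps.norm.sf(np.abs(t))
    return MixedModelFit(
        names=tuple(names), params=params, se=se, tstats=t, pvalues=p,
        random_intercept_sd=sd, loglik=llf, link="identity",
        converged=conv, n_obs=int(len(y)),
        n_groups=int(data[individual_col].nunique()),
    )


def ttest_vs_expected(lambda_maxes, expected: float, n_comparisons: int = 1) -> dict:
    """One-sample t-test of per-cell lambda-max against an expected tuning,
    with Bonferroni correction over ``n_comparisons`` tests."""
    x = np.asarray(lambda_maxes, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 cells for a t-test")
    if np.allclose(x.std(ddof=1), 0.0):
        equal = bool(np.allclose(x.mean(), expected))
        return {"t": 0.0 if equal else np.inf, "df": x.size - 1,
                "p": 1.0 if equal else 0.0,
                "p_corrected": 1.0 if equal else 0.0, "mean": float(x.mean())}
    t, p = sps.ttest_1samp(x, expected)
    return {
        "t": float(t),
        "df": int(x.size - 1),
        "p": float(p),
        "p_corrected": float(min(1.0, p * n_comparisons)),
        "mean": float(x.mean()),
    }


def anova_tukey(durations: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA across groups of half-max durations plus Tukey HSD.

    ``durations`` maps group label -> array of per-cell durations (ms).
    Returns the F statistic with its degrees of freedom, the Tukey table,
    and a compact letter display (groups sharing a letter do not differ).
    """
    labels = list(durations)
    arrays = [np.asarray(durations[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 cells each")
    F, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    values = np.concatenate(arrays)
    glabels = np.concatenate([[g] * a.size for g, a in zip(labels, arrays)])
    tuk = pairwise_tukeyhsd(values, glabels, alpha=alpha)
    tuk_df = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    letters = _compact_letter_display(labels, tuk_df)
    return {"F": float(F), "df": (df1, df2), "p": float(p),
            "tukey": tuk_df, "letters": letters}


def _compact_letter_display(labels, tuk_df) -> dict:
    """Insert-and-absorb compact letter display from a Tukey result table."""
    differ = {
        frozenset((r["group1"], r["group2"]))
        for _, r in tuk_df.iterrows()
        if bool(r["reject"])
    }
    letter_sets = []  # each is a set of mutually non-different groups
    for g in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in differ for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return out


def kde_mode_count(values, bandwidth: float | None = None, grid_size: int = 512) -> int:
    """Number of local maxima of a Gaussian KDE (Silverman bandwidth default).

    A dip-style screen for unimodality of a lambda-max distribution: one
    mode is consistent with a single continuously tuned population rather
    than a mixture of discrete opsin-expression states.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("too few values for a mode count")
    sd = x.std(ddof=1)
    if sd == 0:
        return 1
    if bandwidth is None:
        bandwidth = 1.06 * sd * x.size ** (-1 / 5)
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    return int(np.count_nonzero(interior))
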