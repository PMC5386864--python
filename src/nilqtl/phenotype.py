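"""Entry means, broad-sense heritability and phenotypic correlations.

Plot-level trait values from a multi-environment trial are reduced to
per-line least-squares means (LSmeans), variance components are estimated
from the random-effects model

    value = mu + line + env + line x env + error

(env fixed; line and line x env random), and broad-sense heritability on an
entry-mean basis is

    H^2 = sigma2_G / (sigma2_G + sigma2_GE / e + sigma2_e / (e * r))

with e environments and r replicates per environment (harmonic means of the
per-line counts when the data are unbalanced).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityEstimate",
    "CorrelationReport",
    "compute_lsmeans",
    "estimate_heritability",
    "anova_variance_components",
    "phenotypic_correlations",
]

_PLOT_COLUMNS = ("line", "env", "rep", "trait", "value")


def _check_plot_table(plots: pd.DataFrame) -> pd.DataFrame:
    missing = set(_PLOT_COLUMNS) - set(plots.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    dup = plots.duplicated(subset=["line", "env", "rep", "trait"])
    if dup.any():
        row = plots.loc[dup].iloc[0]
        raise ValueError(
            "duplicate plot key "
            f"(line={row['line']!r}, env={row['env']!r}, rep={row['rep']!r}, "
            f"trait={row['trait']!r})"
        )
    return plots.dropna(subset=["value"])


def _lsmeans_one_trait(df: pd.DataFrame) -> pd.Series:
    """LSmeans for one trait from the fixed model value = line + env + error.

    Line effects are absorbed (within-line demeaning), the environment
    contrasts are solved by OLS on the demeaned data, and each line's LSmean
    is its adjusted intercept evaluated at the average environment effect.
    Exactly reproduces the normal-equation solution for connected designs;
    for balanced data it reduces to the per-line arithmetic mean.
    """
    envs = sorted(df["env"].unique())
    lines = df["line"].unique()
    if len(envs) == 1:
        return df.groupby("line", sort=False)["value"].mean().reindex(lines)

    y = df["value"].to_numpy(dtype=float)
    # treatment-coded env dummies (first env = reference)
    X = np.column_stack([(df["env"] == e).to_numpy(float) for e in envs[1:]])
    line_codes, _ = pd.factorize(df["line"])
    n_lines = line_codes.max() + 1
    counts = np.bincount(line_codes, minlength=n_lines).astype(float)

    def demean(v: np.ndarray) -> np.ndarray:
        means = np.bincount(line_codes, weights=v, minlength=n_lines) / counts
        return v - means[line_codes]

    Xd = np.column_stack([demean(X[:, j]) for j in range(X.shape[1])])
    beta, *_ = np.linalg.lstsq(Xd, demean(y), rcond=None)
    adj = y - X @ beta  # remove env contrasts
    line_eff = np.bincount(line_codes, weights=adj, minlength=n_lines) / counts
    # evaluate at the average of the env effects (reference effect is 0)
    ls = line_eff + beta.sum() / len(envs)
    return pd.Series(ls, index=df["line"].unique()[:n_lines]).reindex(lines)


def compute_lsmeans(plots: pd.DataFrame) -> pd.DataFrame:
    """Line x trait table of least-squares means across environments.

    Lines with no observation for a trait are missing in that column (a
    warning is logged).  Replicates are averaged within environment by the
    model's error term; no rep main effect is fitted.
    """
    plots = _check_plot_table(plots)
    all_lines = pd.Index(plots["line"].unique(), name="line")
    out = {}
    for trait, df in plots.groupby("trait", sort=False):
        ls = _lsmeans_one_trait(df)
        absent = all_lines.difference(ls.index)
        if len(absent):
            logger.warning(
                "trait %r: %d line(s) without observations, LSmean set missing",
                trait, len(absent),
            )
        out[trait] = ls.reindex(all_lines)
    return pd.DataFrame(out, index=all_lines)


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    h2: float
    n_env: float
    n_rep: float
    method: str


def _is_balanced(df: pd.DataFrame) -> bool:
    cell = df.groupby(["line", "env"], sort=False)["value"].size()
    if cell.nunique() != 1:
        return False
    n_env = df["env"].nunique()
    per_line = df.groupby("line", sort=False)["env"].nunique()
    return bool((per_line == n_env).all())


def anova_variance_components(df: pd.DataFrame) -> tuple[float, float, float]:
    """Method-of-moments variance components for balanced line x env data.

    Expected-mean-squares solution of the two-way mixed model; for balanced
    data with interior estimates this coincides with REML.  Returns
    (sigma2_g, sigma2_ge, sigma2_e) truncated at zero.
    """
    n_env = df["env"].nunique()
    r = int(df.groupby(["line", "env"])["value"].size().iloc[0])
    line_means = df.groupby("line")["value"].mean()
    env_means = df.groupby("env")["value"].mean()
    cell_means = df.groupby(["line", "env"])["value"].mean()
    grand = df["value"].mean()
    n_lines = line_means.size

    ms_g = n_env * r * line_means.sub(grand).pow(2).sum() / (n_lines - 1)
    if n_env > 1:
        inter = (
            cell_means
            - line_means.reindex(cell_means.index.get_level_values("line")).to_numpy()
            - env_means.reindex(cell_means.index.get_level_values("env")).to_numpy()
            + grand
        )
        ms_ge = r * inter.pow(2).sum() / ((n_lines - 1) * (n_env - 1))
    else:
        ms_ge = np.nan
    if r > 1:
        within = df["value"] - cell_means.reindex(
            pd.MultiIndex.from_frame(df[["line", "env"]])
        ).to_numpy()
        ms_e = within.pow(2).sum() / (n_lines * n_env * (r - 1))
    else:
        ms_e = np.nan

    if n_env > 1 and r > 1:
        s2e = ms_e
        s2ge = (ms_ge - ms_e) / r
        s2g = (ms_g - ms_ge) / (n_env * r)
    elif n_env > 1:  # r == 1: GE and error confounded; report all as error
        s2e = ms_ge
        s2ge = 0.0
        s2g = (ms_g - ms_ge) / n_env
    else:  # single env, r > 1: no GE term estimable
        s2e = ms_e
        s2ge = 0.0
        s2g = (ms_g - ms_e) / r
    return (max(s2g, 0.0), max(s2ge, 0.0), max(s2e, 0.0))


def _reml_variance_components(df: pd.DataFrame) -> tuple[float, float, float]:
    """REML components via a linear mixed model (line and line x env random)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = df.reset_index(drop=True)
    n_env = df["env"].nunique()
    vc = {"gxe": "0 + C(env)"} if n_env > 1 and df["rep"].nunique() > 1 else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "value ~ C(env)", groups="line",
            re_formula="1", vc_formula=vc, data=df,
        )
        fit = model.fit(reml=True)
    s2g = float(np.asarray(fit.cov_re)[0, 0])
    s2ge = float(fit.vcomp[0]) if vc else 0.0
    s2e = float(fit.scale)
    return (max(s2g, 0.0), max(s2ge, 0.0), max(s2e, 0.0))


def _harmonic_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.size / np.sum(1.0 / x))


def estimate_heritability(
    plots: pd.DataFrame,
    trait: str | None = None,
    method: str = "auto",
) -> list[HeritabilityEstimate] | HeritabilityEstimate:
    """Broad-sense heritability on an entry-mean basis, per trait.

    method : {"auto", "reml", "anova"}
        "auto" uses the closed-form expected-mean-squares solution when the
        trial is balanced (where it equals REML) and a numerical REML fit
        otherwise; "anova"/"reml" force one route.

    Raises if neither environments nor replicates are replicated, since the
    genetic variance is then confounded with the plot residual.
    """
    plots = _check_plot_table(plots)
    traits = [trait] if trait is not None else list(plots["trait"].unique())
    results = []
    for tr in traits:
        df = plots[plots["trait"] == tr]
        if df.empty:
            raise ValueError(f"no observations for trait {tr!r}")
        n_env = df["env"].nunique()
        max_rep = df.groupby(["line", "env"])["value"].size().max()
        if n_env == 1 and max_rep == 1:
            raise ValueError(
                f"trait {tr!r}: heritability not estimable from a single "
                "environment with a single replicate"
            )
        use = method
        if method == "auto":
            use = "anova" if _is_balanced(df) else "reml"
        if use == "anova":
            s2g, s2ge, s2e = anova_variance_components(df)
        elif use == "reml":
            s2g, s2ge, s2e = _reml_variance_components(df)
        else:
            raise ValueError(f"unknown method {method!r}")

        per_line_env = df.groupby("line")["env"].nunique()
        per_line_n = df.groupby("line")["value"].size()
        e_h = _harmonic_mean(per_line_env.to_numpy())
        r_h = _harmonic_mean((per_line_n / per_line_env).to_numpy())
        denom = s2g + s2ge / e_h + s2e / (e_h * r_h)
        h2 = s2g / denom if denom > 0 else np.nan
        results.append(
            HeritabilityEstimate(
                trait=tr, sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
                h2=float(h2), n_env=e_h, n_rep=r_h, method=use,
            )
        )
    if trait is not None:
        return results[0]
    return results


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations of entry means, with p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def __str__(self) -> str:
        lines = ["trait_a\ttrait_b\tr\tp\tn"]
        traits = list(self.r.columns)
        for a, b in combinations(traits, 2):
            lines.append(
                f"{a}\t{b}\t{self.r.loc[a, b]:.4g}\t{self.p.loc[a, b]:.3g}"
                f"\t{int(self.n.loc[a, b])}"
            )
        return "\n".join(lines)


def phenotypic_correlations(lsmeans: pd.DataFrame, min_pairs: int = 3) -> CorrelationReport:
    """Pairwise-complete Pearson correlations between trait LSmeans.

    Uses the t-distribution two-sided p-value.  Trait pairs with fewer than
    ``min_pairs`` complete observations, or a constant trait, yield missing
    entries with a logged warning.
    """
    traits = list(lsmeans.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    n = pd.DataFrame(
        np.diag(lsmeans.notna().sum().to_numpy()).astype(float),
        index=traits, columns=traits,
    )
    for a, b in combinations(traits, 2):
        pair = lsmeans[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < min_pairs:
            logger.warning("traits %r/%r: fewer than %d complete pairs", a, b, min_pairs)
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        if pair[a].nunique() == 1 or pair[b].nunique() == 1:
            logger.warning("traits %r/%r: constant values, correlation undefined", a, b)
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return CorrelationReport(r=r, p=p, n=n)
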