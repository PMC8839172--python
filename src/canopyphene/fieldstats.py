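"""Field-trial statistics: outlier screening, normalising transforms, balanced
factorial ANOVA with generalized eta squared, standardized pairwise contrasts,
cross-repetition consistency filtering, trait correlations, PCA and
hierarchical clustering of genotypes.

The trial model is ``trait ~ treatment × genotype + block`` with a fixed
additive block term.  For a complete balanced split-plot realisation the
F-tests for treatment, genotype and their interaction coincide with the
random-block mixed model, and estimated marginal means equal cell means, so
the module stays free of iterative variance-component fitting; a warning is
raised when the design is unbalanced.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "iqr_outliers",
    "apply_transform",
    "inverse_transform",
    "factorial_anova",
    "generalized_eta_squared",
    "pairwise_effect_sizes",
    "consistent_contrasts",
    "correlate_traits",
    "pca_traits",
    "cluster_genotypes",
]


# --------------------------------------------------------------------------
# outliers and transforms
# --------------------------------------------------------------------------

def iqr_outliers(
    values: pd.Series | np.ndarray,
    groups: pd.DataFrame | pd.Series | None = None,
    k: float = 1.5,
    min_group: int = 4,
) -> np.ndarray:
    """Flag values outside [Q1 − k·IQR, Q3 + k·IQR] within each group.

    Quartiles use linear interpolation.  Groups with fewer than ``min_group``
    values are skipped with a warning (nothing flagged there).
    """
    values = pd.Series(np.asarray(values, dtype=float))
    flags = np.zeros(len(values), dtype=bool)
    if groups is None:
        group_iter = [(None, values.index)]
    else:
        gdf = pd.DataFrame(groups).reset_index(drop=True)
        group_iter = list(gdf.groupby(list(gdf.columns), observed=True).groups.items())
    for name, idx in group_iter:
        v = values.loc[idx]
        if len(v) < min_group:
            warnings.warn(
                f"group {name!r} has {len(v)} < {min_group} values; skipped",
                stacklevel=2,
            )
            continue
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flags[np.asarray(idx)] = (v < lo) | (v > hi)
    return flags


_TRANSFORMS = {
    "none": (lambda x: x, lambda x: x),
    "log": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
    "reciprocal": (lambda x: 1.0 / x, lambda x: 1.0 / x),
}


def apply_transform(values, transform: str = "none"):
    """Elementwise normalising transform; see ``inverse_transform``."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    values = np.asarray(values, dtype=float)
    if transform in ("log", "sqrt") and np.any(values < 0):
        bad = np.flatnonzero(values < 0)
        raise ValueError(f"{transform} transform: negative values at records {bad[:10].tolist()}")
    if transform in ("log", "reciprocal") and np.any(values == 0):
        bad = np.flatnonzero(values == 0)
        raise ValueError(f"{transform} transform: zero values at records {bad[:10].tolist()}")
    return _TRANSFORMS[transform][0](values)


def inverse_transform(values, transform: str = "none"):
    """Back-transform values for reporting on the original scale."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    return _TRANSFORMS[transform][1](np.asarray(values, dtype=float))


# --------------------------------------------------------------------------
# ANOVA and effect sizes
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-term sums of squares, df, F, p plus design metadata.

    ``table`` is indexed by term name (e.g. ``treatment``,
    ``treatment:genotype``, ``Residual``) with columns sum_sq, df, F, p.
    """

    table: pd.DataFrame
    response: str
    factors: list[str]
    block: str | None
    balanced: bool
    n_obs: int

    @property
    def residual_ms(self) -> float:
        res = self.table.loc["Residual"]
        return float(res["sum_sq"] / res["df"])

    def term_ss(self, term: str) -> float:
        return float(self.table.loc[term, "sum_sq"])


def _check_balanced(data: pd.DataFrame, cols: list[str]) -> bool:
    counts = data.groupby(cols, observed=True).size()
    full = np.prod([data[c].nunique() for c in cols])
    return len(counts) == full and counts.nunique() == 1


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    block: str | None = None,
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with all interactions among ``factors``
    and an optional additive block term.

    Empty factor-level cells raise an error naming them.  An unbalanced (but
    complete) design falls back to type-III-equivalent sums of squares with a
    warning; in the balanced case type I/II/III coincide.
    """
    data = data.reset_index(drop=True)
    counts = data.groupby(list(factors), observed=True).size()
    full = np.prod([data[f].nunique() for f in factors])
    if len(counts) < full:
        have = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        levels = [sorted(data[f].unique()) for f in factors]
        missing = [c for c in itertools.product(*levels) if c not in have]
        raise ValueError(f"empty design cells: {missing[:5]}")
    balanced = counts.nunique() == 1 and (
        block is None or _check_balanced(data, list(factors) + [block])
    )

    terms = " * ".join(f"C({f})" for f in factors)
    formula = f"Q('{response}') ~ {terms}"
    if block is not None:
        formula += f" + C({block})"
    model = smf.ols(formula, data=data).fit()
    if balanced:
        tab = anova_lm(model, typ=2)
    else:
        warnings.warn("unbalanced design: using type-III sums of squares", stacklevel=2)
        tab = anova_lm(model, typ=3)
        tab = tab.drop(index="Intercept", errors="ignore")

    # rename C(a):C(b) -> a:b for readability
    def clean(term: str) -> str:
        return ":".join(p[2:-1] if p.startswith("C(") else p for p in term.split(":"))

    tab = tab.rename(index=clean)
    tab = tab.rename(columns={"PR(>F)": "p"})
    tab = tab[["sum_sq", "df", "F", "p"]]
    return AnovaResult(
        table=tab,
        response=response,
        factors=list(factors),
        block=block,
        balanced=bool(balanced),
        n_obs=len(data),
    )


def generalized_eta_squared(
    anova: AnovaResult, measured_factors: set[str] | None = None
) -> pd.Series:
    """Generalized eta squared per term (Olejnik–Algina scheme).

    η²_G = SS_effect / (δ·SS_effect + Σ SS over measured terms + SS_error),
    where a term counts as measured iff it involves at least one factor in
    ``measured_factors`` (interactions with manipulated factors included) and
    δ = 1 only when the effect itself is purely manipulated.  With all factors
    manipulated and a single error stratum this reduces to
    SS_effect / (SS_effect + SS_residual).
    """
    measured = set(measured_factors or ())
    known = set(anova.factors) | ({anova.block} if anova.block else set())
    unknown = measured - known
    if unknown:
        raise ValueError(f"unknown factor label(s): {sorted(unknown)}")
    tab = anova.table
    ss_error = float(tab.loc["Residual", "sum_sq"])

    def is_measured(term: str) -> bool:
        parts = term.split(":")
        return bool(measured) and any(p in measured for p in parts)

    ss_measured_total = sum(
        float(tab.loc[t, "sum_sq"]) for t in tab.index
        if t != "Residual" and is_measured(t)
    )
    out = {}
    for term in tab.index:
        if term == "Residual":
            continue
        ss = float(tab.loc[term, "sum_sq"])
        denom = ss_error + ss_measured_total
        if not is_measured(term):
            denom += ss
        out[term] = ss / denom if denom > 0 else 0.0
    return pd.Series(out, name="ges")


def pairwise_effect_sizes(
    data: pd.DataFrame,
    response: str,
    group: str = "genotype",
    within: str | None = "treatment",
    sd_pooled: float | None = None,
    anova: AnovaResult | None = None,
) -> pd.DataFrame:
    """Standardized pairwise contrasts d = (mean_a − mean_b)/SD.

    Cell means are estimated marginal means, which in a balanced design equal
    arithmetic cell means.  The standardiser defaults to the root residual
    mean square of the supplied (or internally fitted) ANOVA.
    """
    if sd_pooled is None:
        if anova is None:
            factors = [group] + ([within] if within else [])
            anova = factorial_anova(data, response, factors)
        sd_pooled = float(np.sqrt(anova.residual_ms))
    if sd_pooled <= 0:
        raise ValueError("pooled SD must be positive")
    strata = data.groupby(within, observed=True) if within else [(None, data)]
    rows = []
    for stratum, sub in strata:
        means = sub.groupby(group, observed=True)[response].mean()
        for a, b in itertools.combinations(sorted(means.index), 2):
            d = (means[a] - means[b]) / sd_pooled
            rows.append(
                {
                    within or "stratum": stratum,
                    "a": a,
                    "b": b,
                    "d": float(d),
                }
            )
    return pd.DataFrame(rows)


def consistent_contrasts(
    effect_tables: dict, threshold: float = 1.0
) -> pd.DataFrame:
    """Keep (pair, stratum) contrasts with |d| > threshold in every repetition.

    ``effect_tables`` maps repetition label → the ``pairwise_effect_sizes``
    output (same pair grid in each).  Returns the edge list with per-rep d
    values, analogous to a bipartite contrast graph.
    """
    if not effect_tables:
        raise ValueError("no repetitions supplied")
    reps = sorted(effect_tables)
    key_cols = [c for c in effect_tables[reps[0]].columns if c != "d"]
    merged = None
    for rep in reps:
        t = effect_tables[rep]
        if set(t.columns) != set(key_cols) | {"d"}:
            raise ValueError("repetition tables have mismatched columns")
        t = t.rename(columns={"d": f"d_{rep}"})
        merged = t if merged is None else merged.merge(t, on=key_cols, how="outer")
    d_cols = [f"d_{rep}" for rep in reps]
    if merged[d_cols].isna().any().any():
        raise ValueError("missing contrasts in at least one repetition")
    keep = (merged[d_cols].abs() > threshold).all(axis=1)
    return merged[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# correlations, ordination, clustering
# --------------------------------------------------------------------------

def correlate_traits(
    traits: pd.DataFrame, alpha: float = 0.05, normality_alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise trait correlations with distribution-dependent method choice.

    Each margin is tested with Shapiro–Wilk; Pearson is used when both pass at
    ``normality_alpha``, Spearman otherwise.  Constant traits give masked
    (NaN) correlations.  ``significant`` flags p < ``alpha``.
    """
    cols = list(traits.columns)
    normal = {}
    for c in cols:
        v = traits[c].dropna()
        normal[c] = (
            len(v) >= 4
            and v.std() > 0
            and stats.shapiro(v).pvalue > normality_alpha
        )
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = traits[[a, b]].dropna()
        if len(sub) < 4 or sub[a].std() == 0 or sub[b].std() == 0:
            rows.append({"a": a, "b": b, "r": np.nan, "p": np.nan,
                         "method": "undefined", "significant": False})
            continue
        if normal[a] and normal[b]:
            r, p = stats.pearsonr(sub[a], sub[b])
            method = "pearson"
        else:
            r, p = stats.spearmanr(sub[a], sub[b])
            method = "spearman"
        rows.append({"a": a, "b": b, "r": float(r), "p": float(p),
                     "method": method, "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def pca_traits(means: pd.DataFrame, scale: bool = True):
    """PCA of genotype × treatment trait means (column-standardised).

    Returns (scores, loadings, variance_fractions); loadings are orthonormal
    and variance fractions sum to 1 over the returned components.
    """
    X = means.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing cells in the trait mean matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if scale:
        if np.any(sd == 0):
            raise ValueError("constant trait column cannot be scaled")
        X = (X - mu) / sd
    else:
        X = X - mu
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    scores = pd.DataFrame(
        scores, index=means.index, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    loadings = pd.DataFrame(
        pca.components_.T, index=means.columns, columns=scores.columns
    )
    total_var = X.var(axis=0, ddof=1).sum()
    var_frac = pca.explained_variance_ / total_var
    return scores, loadings, var_frac


def cluster_genotypes(
    scaled_means: pd.DataFrame, k: int = 5, method: str = "average"
):
    """Agglomerative hierarchical clustering of scaled trait-mean rows.

    Euclidean distances, configurable linkage (``average`` by default), tree
    cut at ``k`` clusters.  Returns (labels Series, scipy linkage matrix).
    """
    X = scaled_means.to_numpy(dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} observations, got {X.shape[0]}")
    Z = linkage(X, method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=scaled_means.index, name="cluster"), Z
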