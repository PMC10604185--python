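"""Morphometric trait refinement, PCA on population means, and per-trait
association with elevation.

The refinement pipeline mirrors a standard field-morphometry workflow:

1. drop individuals with any missing measurement (listwise deletion);
2. per trait, choose a parametric (ANOVA + Tukey-Kramer) or non-parametric
   (Kruskal-Wallis + pairwise Mann-Whitney U, Bonferroni) omnibus route via a
   Brown-Forsythe homoscedasticity test, and discard traits that do not
   discriminate among populations;
3. build the population-mean matrix;
4. greedily prune traits until no retained pair has |Pearson r| above the
   cutoff on population means;
5. z-score the retained population-mean columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import SiteTable, TraitTable, ValidationError

__all__ = [
    "levene_test",
    "among_population_test",
    "refine_traits",
    "pca_population_means",
    "elevation_association",
    "AmongPopulationResult",
    "RefinedTraitSet",
    "PCAResult",
    "ElevationAssociation",
]


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValidationError(f"group {g!r} has no non-missing values")
        out[str(g)] = v
    return out


def levene_test(values, groups) -> tuple[float, float]:
    """Brown-Forsythe homoscedasticity test.

    One-way ANOVA F on absolute deviations from each group's median;
    returns ``(statistic, p_value)``.
    """
    split = _split_groups(values, groups)
    if len(split) < 2 or any(v.size < 2 for v in split.values()):
        raise ValidationError("need >= 2 groups with >= 2 non-missing values each")
    stat, p = stats.levene(*split.values(), center="median")
    if not np.isfinite(stat):  # all deviations identical
        stat, p = 0.0, 1.0
    return float(stat), float(p)


@dataclass
class AmongPopulationResult:
    """Omnibus among-population test with a pairwise post hoc matrix."""

    method: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame  # symmetric matrix of corrected pairwise p-values
    discriminating: bool
    alpha: float


def among_population_test(values, groups, homoscedastic: bool, alpha: float = 0.01) -> AmongPopulationResult:
    """Test whether a trait differs among populations.

    Homoscedastic data get one-way ANOVA with Tukey-Kramer pairwise
    comparisons; otherwise Kruskal-Wallis with pairwise Mann-Whitney U tests
    Bonferroni-corrected over all pairs.  A trait is *discriminating* iff the
    omnibus p-value is below ``alpha``.
    """
    split = _split_groups(values, groups)
    if len(split) < 2 or any(v.size < 2 for v in split.values()):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    labels = list(split)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    posthoc = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)

    all_values = np.concatenate(list(split.values()))
    if np.ptp(all_values) == 0.0:  # constant trait: nothing to discriminate
        method = "anova" if homoscedastic else "kruskal"
        return AmongPopulationResult(method, 0.0, 1.0, posthoc, False, alpha)

    if homoscedastic:
        stat, p = stats.f_oneway(*split.values())
        flat = np.concatenate([np.repeat(l, split[l].size) for l in labels])
        tk = pairwise_tukeyhsd(all_values, flat, alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            posthoc.loc[str(row["group1"]), str(row["group2"])] = float(row["p-adj"])
            posthoc.loc[str(row["group2"]), str(row["group1"])] = float(row["p-adj"])
        method = "anova"
    else:
        stat, p = stats.kruskal(*split.values())
        for a, b in itertools.combinations(labels, 2):
            _, p_ab = stats.mannwhitneyu(split[a], split[b], alternative="two-sided")
            p_corr = min(1.0, p_ab * n_pairs)
            posthoc.loc[a, b] = posthoc.loc[b, a] = p_corr
        method = "kruskal"
    np.fill_diagonal(posthoc.values, 1.0)
    return AmongPopulationResult(method, float(stat), float(p), posthoc, bool(p < alpha), alpha)


@dataclass
class RefinedTraitSet:
    """Outcome of the trait-refinement pipeline."""

    populations: list[str]
    retained_traits: list[str]
    pop_means: pd.DataFrame      # populations x retained traits, raw units
    pop_means_z: pd.DataFrame    # populations x retained traits, z-scored
    dropped_nonsignificant: list[str]
    dropped_correlated: list[str]
    dropped_samples: list[str]
    test_summary: pd.DataFrame = field(default=None, repr=False)  # per-trait p-values

    def summary_dict(self) -> dict:
        return {
            "retained": self.retained_traits,
            "dropped_nonsignificant": self.dropped_nonsignificant,
            "dropped_correlated": self.dropped_correlated,
            "dropped_samples": self.dropped_samples,
        }


def _greedy_prune(means: pd.DataFrame, r_max: float, trait_order: list[str]) -> list[str]:
    """Drop traits until no pair of population-mean columns has |r| > r_max.

    At each step the worst-offending pair is found; the member with the
    larger mean absolute correlation to all other remaining traits is
    dropped, ties broken toward the trait appearing later in the original
    column order.
    """
    retained = list(means.columns)
    dropped: list[str] = []
    while len(retained) > 1:
        corr = means[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        i, j = np.unravel_index(np.nanargmax(absr), absr.shape)
        if not absr[i, j] > r_max:
            break
        mean_abs = np.nanmean(absr, axis=1)
        if not np.isclose(mean_abs[i], mean_abs[j]):
            victim = i if mean_abs[i] > mean_abs[j] else j
        else:  # tie: later original position goes
            victim = max(i, j, key=lambda t: trait_order.index(retained[t]))
        dropped.append(retained.pop(victim))
    return dropped


def refine_traits(
    t: TraitTable,
    alpha_levene: float = 0.05,
    alpha_test: float = 0.01,
    r_max: float = 0.8,
) -> RefinedTraitSet:
    """Run the full refinement pipeline on a raw trait table."""
    if len(t.population_labels) < 2:
        raise ValidationError("refinement needs at least 2 populations")
    complete = ~t.data.isna().any(axis=1)
    dropped_samples = [s for s, ok in zip(t.samples, complete) if not ok]
    data = t.data.loc[complete.to_numpy()]
    pops = np.asarray(t.populations)[complete.to_numpy()]

    rows = []
    dropped_ns: list[str] = []
    for trait in t.traits:
        _, p_lev = levene_test(data[trait], pops)
        res = among_population_test(data[trait], pops, homoscedastic=p_lev >= alpha_levene,
                                    alpha=alpha_test)
        rows.append({"trait": trait, "levene_p": p_lev, "method": res.method,
                     "omnibus_p": res.p_value, "discriminating": res.discriminating})
        if not res.discriminating:
            dropped_ns.append(trait)
    summary = pd.DataFrame(rows).set_index("trait")
    kept = [tr for tr in t.traits if tr not in dropped_ns]
    if len(kept) < 2:
        raise ValidationError(f"fewer than 2 traits discriminate among populations ({kept})")

    frame = pd.DataFrame(data[kept])
    frame["__pop"] = pops
    means = frame.groupby("__pop", sort=False).mean()
    means.index.name = "population"

    dropped_corr = _greedy_prune(means, r_max, trait_order=list(t.traits))
    retained = [tr for tr in kept if tr not in dropped_corr]
    if len(retained) < 2:
        raise ValidationError("fewer than 2 traits retained after correlation pruning")
    means = means[retained]
    z = (means - means.mean()) / means.std(ddof=1)
    return RefinedTraitSet(
        populations=list(means.index),
        retained_traits=retained,
        pop_means=means,
        pop_means_z=z,
        dropped_nonsignificant=dropped_ns,
        dropped_correlated=dropped_corr,
        dropped_samples=dropped_samples,
        test_summary=summary,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame     # populations x components
    loadings: pd.DataFrame   # traits x components
    explained: np.ndarray    # proportion of variance per component

    @property
    def n_components(self) -> int:
        return len(self.explained)


def pca_population_means(r: RefinedTraitSet | pd.DataFrame) -> PCAResult:
    """PCA of the z-scored population-mean matrix via SVD.

    Components are ordered by decreasing explained variance; only components
    with non-zero singular value are kept (their explained proportions sum
    to 1).  Sign convention: the largest-magnitude loading of each component
    is positive.
    """
    X = r.pop_means_z if isinstance(r, RefinedTraitSet) else r
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValidationError("PCA needs >= 3 populations and >= 2 traits")
    centered = X.to_numpy(float) - X.to_numpy(float).mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    keep = S > S[0] * 1e-12 if S[0] > 0 else np.zeros_like(S, bool)
    if not keep.any():
        raise ValidationError("input matrix has rank 0")
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    # deterministic sign: largest |loading| per component is positive
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    names = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=X.index, columns=names),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=names),
        explained=S**2 / (S**2).sum(),
    )


@dataclass
class ElevationAssociation:
    trait: str
    rho: float
    p_value: float
    fit_degree: int
    adj_r2: float
    F_stat: float
    fit_p: float
    excluded_populations: list[str]
    coefficients: np.ndarray = field(default=None, repr=False)  # highest degree first


def elevation_association(
    r: RefinedTraitSet | pd.DataFrame,
    sites: SiteTable,
    trait: str,
    degree: int = 1,
    exclude: tuple[str, ...] = (),
) -> ElevationAssociation:
    """Spearman correlation and polynomial regression of a trait on elevation.

    Operates on population means; ``exclude`` removes populations (e.g. a
    known outlier site) before both the correlation and the fit.
    """
    if degree not in (1, 2):
        raise ValidationError("fit degree must be 1 or 2")
    means = r.pop_means if isinstance(r, RefinedTraitSet) else r
    if trait not in means.columns:
        raise ValidationError(f"trait {trait!r} not present")
    pops = [p for p in means.index if p not in exclude]
    if len(pops) < 4:
        raise ValidationError("fewer than 4 populations after exclusions")
    y = means.loc[pops, trait].to_numpy(float)
    x = sites.data.loc[pops, "elevation"].to_numpy(float)

    rho, p = stats.spearmanr(x, y)
    coef = np.polyfit(x, y, degree)
    pred = np.polyval(coef, x)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, k = len(y), degree
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    if r2 >= 1.0 - 1e-12:  # numerically exact fit
        F, fit_p = np.inf, 0.0
    else:
        F = (r2 / k) / ((1.0 - r2) / (n - k - 1))
        fit_p = float(stats.f.sf(F, k, n - k - 1))
    return ElevationAssociation(
        trait=trait, rho=float(rho), p_value=float(p), fit_degree=degree,
        adj_r2=float(adj_r2), F_stat=float(F), fit_p=fit_p,
        excluded_populations=list(exclude), coefficients=coef,
    )
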