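"""Neutral-locus differentiation: Nei pairwise Fst, a global estimate with
locus-bootstrap confidence intervals, and the Evanno delta-K helper.

Pairwise Fst follows Nei (1987): per locus, H_S is the mean within-population
expected heterozygosity with the 2n/(2n-1) small-sample correction and H_T the
expected heterozygosity of the mean allele frequency of the pair;
heterozygosities are averaged over loci before forming (H_T - H_S)/H_T.
Loci lacking a call in either population of a pair are excluded pairwise.

The global estimate uses Weir & Cockerham (1984) variance components
(theta = sum(a) / sum(a+b+c) over loci), which is close to unbiased for the
dispersal parameter of a Balding-Nichols population model, with a percentile
bootstrap over loci for the confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, SymmetricMatrix, ValidationError

__all__ = [
    "population_allele_stats",
    "nei_pairwise_fst",
    "global_fst_ci",
    "evanno_delta_k",
    "FstResult",
    "DeltaKTable",
]


@dataclass
class FstResult:
    """Global Fst with bootstrap CI plus the pairwise Nei matrix."""

    pairwise: SymmetricMatrix
    global_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    confidence: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": self.global_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "confidence": self.confidence,
            "seed": self.seed,
        }


@dataclass
class DeltaKTable:
    """Evanno second-order statistic over a ladder of K values."""

    K: np.ndarray
    mean_lnP: np.ndarray
    sd_lnP: np.ndarray
    delta_K: np.ndarray  # NaN at the two edge K values
    best_K: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.K, "mean_lnP": self.mean_lnP,
             "sd_lnP": self.sd_lnP, "delta_K": self.delta_K}
        )


def population_allele_stats(g: GenotypeMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-population, per-locus ALT frequency and called-sample count.

    Returns ``(labels, freq, count)`` where ``freq`` is ``(k, L)`` with NaN
    where a population has no call at a locus, and ``count`` the number of
    non-missing genotypes.
    """
    labels = g.population_labels
    idx = g.population_indices()
    k, L = len(labels), g.n_loci
    freq = np.full((k, L), np.nan)
    count = np.zeros((k, L), dtype=int)
    for a, pop in enumerate(labels):
        dos = g.dosages[idx[pop]].astype(float)
        called = dos != MISSING
        count[a] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.where(called, dos, 0.0).sum(axis=0)
            freq[a] = np.where(count[a] > 0, sums / (2.0 * np.maximum(count[a], 1)), np.nan)
    dead = [labels[a] for a in range(k) if (count[a] == 0).all()]
    if dead:
        raise ValidationError(f"population(s) with zero genotype calls at every locus: {dead}")
    return labels, freq, count


def _het_counts(g: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Observed-heterozygote proportion per population per locus (NaN if no calls)."""
    labels = g.population_labels
    idx = g.population_indices()
    het = np.full((len(labels), g.n_loci), np.nan)
    for a, pop in enumerate(labels):
        dos = g.dosages[idx[pop]]
        called = (dos != MISSING).sum(axis=0)
        nhet = (dos == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            het[a] = np.where(called > 0, nhet / np.maximum(called, 1), np.nan)
    return labels, het


def nei_pairwise_fst(g: GenotypeMatrix, truncate_negative: bool = False) -> SymmetricMatrix:
    """Pairwise Nei (1987) Fst between all population pairs."""
    labels, freq, count = population_allele_stats(g)
    if len(labels) < 2:
        raise ValidationError("pairwise Fst needs at least 2 populations")
    k = len(labels)
    out = np.zeros((k, k))
    for a, b in combinations(range(k), 2):
        usable = (count[a] > 0) & (count[b] > 0)
        if not usable.any():
            raise ValidationError(
                f"no shared genotyped locus for pair ({labels[a]}, {labels[b]})"
            )
        pa, pb = freq[a, usable], freq[b, usable]
        na, nb = count[a, usable], count[b, usable]
        hs_a = 2.0 * pa * (1.0 - pa) * (2.0 * na) / (2.0 * na - 1.0)
        hs_b = 2.0 * pb * (1.0 - pb) * (2.0 * nb) / (2.0 * nb - 1.0)
        hs = 0.5 * (hs_a + hs_b)
        pbar = 0.5 * (pa + pb)
        ht = 2.0 * pbar * (1.0 - pbar)
        mean_ht = ht.mean()
        if mean_ht <= 0:
            fst = 0.0
        else:
            fst = (mean_ht - hs.mean()) / mean_ht
        if truncate_negative:
            fst = max(fst, 0.0)
        out[a, b] = out[b, a] = fst
    return SymmetricMatrix(labels=labels, values=out, kind="genetic_fst")


def weir_cockerham_components(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components.

    Returns ``(a, abc)`` arrays over usable loci, where the multi-locus
    estimate is ``sum(a) / sum(abc)``.  Loci genotyped in fewer than two
    populations are dropped.
    """
    labels, freq, count = population_allele_stats(g)
    _, het = _het_counts(g)
    n = count.astype(float)  # (k, L)
    present = n > 0
    r = present.sum(axis=0).astype(float)  # populations with data per locus
    usable = r >= 2
    if not usable.any():
        raise ValidationError("no locus genotyped in at least two populations")
    n = n[:, usable]
    p = np.where(present[:, usable], freq[:, usable], 0.0)
    h = np.where(present[:, usable], het[:, usable], 0.0)
    r = r[usable]

    nsum = n.sum(axis=0)
    nbar = nsum / r
    nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1.0)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n * h).sum(axis=0) / nsum

    # Guard: loci where every population has a single sample (nbar == 1)
    ok = nbar > 1.0
    nbar, nc, pbar, s2, hbar, r = (x[ok] for x in (nbar, nc, pbar, s2, hbar, r))
    if nbar.size == 0:
        raise ValidationError("every locus has at most one call per population")

    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, a + b + c


def global_fst_ci(
    g: GenotypeMatrix,
    n_boot: int = 1000,
    confidence: float = 0.99,
    seed: int | None = None,
    truncate_negative: bool = False,
) -> FstResult:
    """Global Fst from variance components with a locus-bootstrap CI.

    The point estimate is the multi-locus Weir-Cockerham theta; the CI is a
    percentile bootstrap resampling loci with replacement ``n_boot`` times.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    if not 0.0 < confidence < 1.0:
        raise ValidationError("confidence must be in (0, 1)")
    a, abc = weir_cockerham_components(g)
    L = a.size
    if L < 2:
        raise ValidationError("bootstrap over loci needs at least 2 usable loci")
    estimate = float(a.sum() / abc.sum())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    boot_num = a[idx].sum(axis=1)
    boot_den = abc[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = np.where(boot_den != 0, boot_num / boot_den, 0.0)
    alpha = (1.0 - confidence) / 2.0
    ci_low = float(np.quantile(boot, alpha))
    ci_high = float(np.quantile(boot, 1.0 - alpha))
    if truncate_negative:
        estimate, ci_low, ci_high = (max(x, 0.0) for x in (estimate, ci_low, ci_high))
    return FstResult(
        pairwise=nei_pairwise_fst(g, truncate_negative=truncate_negative),
        global_estimate=estimate,
        ci_low=min(ci_low, estimate),
        ci_high=max(ci_high, estimate),
        n_boot=n_boot,
        confidence=confidence,
        seed=seed,
    )


def evanno_delta_k(lnP: pd.DataFrame) -> DeltaKTable:
    """Evanno's delta-K from replicate clustering log-probabilities.

    Parameters
    ----------
    lnP
        Long-format table with columns ``K`` and ``lnP``, one row per
        replicate run.  Requires at least 3 consecutive K values with at
        least 2 replicates each.

    The statistic at an interior K is
    ``|mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))`` with the sample
    standard deviation across replicates.
    """
    if not {"K", "lnP"} <= set(lnP.columns):
        raise ValidationError("lnP table needs columns 'K' and 'lnP'")
    grouped = lnP.groupby("K")["lnP"]
    Ks = np.array(sorted(grouped.groups))
    if len(Ks) < 3 or not (np.diff(Ks) == 1).all():
        raise ValidationError("need at least 3 consecutive K values")
    counts = grouped.count()
    if (counts < 2).any():
        raise ValidationError("need at least 2 replicates per K")
    mean = grouped.mean().loc[Ks].to_numpy()
    sd = grouped.std(ddof=1).loc[Ks].to_numpy()

    delta = np.full(len(Ks), np.nan)
    for i in range(1, len(Ks) - 1):
        if sd[i] == 0:
            raise ValidationError(f"zero replicate spread at interior K={Ks[i]}: delta-K undefined")
        delta[i] = abs(mean[i + 1] - 2.0 * mean[i] + mean[i - 1]) / sd[i]
    best = int(Ks[int(np.nanargmax(delta))])
    return DeltaKTable(K=Ks, mean_lnP=mean, sd_lnP=sd, delta_K=delta, best_K=best)
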