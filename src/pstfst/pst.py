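"""Pst estimation and the Pst-Fst drift criterion.

Pst quantifies among-population differentiation of a quantitative trait
measured in the wild:

    Pst = (c/h^2) * sigma2_B / ((c/h^2) * sigma2_B + 2 * sigma2_W)

where ``sigma2_B`` and ``sigma2_W`` are the between- and within-population
variance components of the trait, ``c`` the assumed proportion of the
between-population variance that is additive-genetic and ``h^2`` the assumed
narrow-sense heritability within populations.  Since neither c nor h^2 can be
measured in the field, Pst is scanned over a grid of c/h^2 values; drift is
considered an insufficient explanation for the trait when the Pst confidence
band separates from the Fst band already at small c/h^2 (here: at or below
c/h^2 = 0.5).

Variance components come from the unbalanced one-way random-effects ANOVA
with the n0 correction for unequal group sizes; confidence intervals from a
stratified bootstrap resampling individuals within populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import FstResult
from .types import ValidationError

__all__ = [
    "variance_components",
    "pst",
    "pst_from_reference",
    "pst_bootstrap",
    "pst_scan",
    "drift_assessment",
    "VarianceComponents",
    "PstCurve",
    "DriftVerdict",
]


@dataclass
class VarianceComponents:
    """One-way random-effects components of a trait (trait units squared)."""

    sigma2_B: float
    sigma2_W: float
    n_populations: int
    n0: float
    truncated: bool = False  # True when a negative sigma2_B was clipped to 0


@dataclass
class PstCurve:
    """Per-trait Pst point estimates and CI bounds over a c/h^2 grid."""

    trait: str
    grid: np.ndarray
    pst: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    confidence: float
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "c_over_h2": self.grid, "pst": self.pst,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })

    def at(self, c_over_h2: float) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) at the closest grid value."""
        i = int(np.argmin(np.abs(self.grid - c_over_h2)))
        return float(self.pst[i]), float(self.ci_low[i]), float(self.ci_high[i])


@dataclass
class DriftVerdict:
    """Outcome of the CI-overlap criterion for one trait."""

    trait: str
    critical_c_over_h2: float | None  # smallest grid value with Pst CI above Fst CI
    drift_excluded: bool
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {"trait": self.trait, "critical_c_over_h2": self.critical_c_over_h2,
                "drift_excluded": self.drift_excluded, "threshold": self.threshold}


def _group_arrays(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        v = values[groups == g]
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValidationError(f"population {g!r} has fewer than 2 non-missing values")
        out.append(v)
    if len(out) < 2:
        raise ValidationError("need at least 2 populations")
    return out


def _components_from_groups(arrs: list[np.ndarray]) -> VarianceComponents:
    k = len(arrs)
    ns = np.array([a.size for a in arrs], dtype=float)
    N = ns.sum()
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k)
    n0 = (N - (ns**2).sum() / N) / (k - 1)
    s2_b = (ms_b - ms_w) / n0
    truncated = s2_b < 0
    return VarianceComponents(
        sigma2_B=max(s2_b, 0.0), sigma2_W=ms_w,
        n_populations=k, n0=float(n0), truncated=bool(truncated),
    )


def variance_components(values, groups) -> VarianceComponents:
    """Between/within variance components of a trait across populations.

    Uses the unbalanced one-way random-effects ANOVA estimators:
    ``sigma2_W = MS_within`` and ``sigma2_B = (MS_between - MS_within)/n0``
    with ``n0 = (N - sum(n_i^2)/N)/(k-1)``; a negative between-component is
    truncated to zero and flagged.
    """
    return _components_from_groups(_group_arrays(values, groups))


def pst(vc: VarianceComponents, c_over_h2: float) -> float:
    """Evaluate Pst for given components at one c/h^2 value."""
    if c_over_h2 < 0:
        raise ValidationError("c/h^2 must be non-negative")
    if vc.sigma2_B + vc.sigma2_W <= 0:
        raise ValidationError("Pst undefined: both variance components are zero")
    num = c_over_h2 * vc.sigma2_B
    den = num + 2.0 * vc.sigma2_W
    if den == 0.0:
        return 1.0 if num > 0 else 0.0
    return num / den


def pst_from_reference(p_ref: float, ratio_ref: float, ratio_new: float) -> float:
    """Re-evaluate a known Pst at a different c/h^2 ratio.

    Pst odds are proportional to c/h^2 (``Pst/(1-Pst) = (c/h^2) *
    sigma2_B / (2 sigma2_W)``), so a Pst reported at one ratio determines the
    whole curve.  Useful for checking published values at other ratios.
    """
    if not 0.0 < p_ref < 1.0:
        raise ValidationError("reference Pst must be strictly inside (0, 1)")
    if ratio_ref <= 0 or ratio_new < 0:
        raise ValidationError("ratios must be positive (reference) / non-negative (new)")
    odds = p_ref / (1.0 - p_ref) * (ratio_new / ratio_ref)
    return odds / (1.0 + odds)


def _bootstrap_components(
    arrs: list[np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised bootstrap of (sigma2_B, sigma2_W) over replicates.

    Stratified: individuals are resampled with replacement within each
    population, preserving population sizes.  Unstratified: individuals are
    resampled from the pooled sample keeping their population labels, so
    group sizes vary (populations emptied below 2 members make that
    replicate fall back to a fresh draw).
    """
    ns = np.array([a.size for a in arrs])
    k = len(arrs)
    N = int(ns.sum())
    if stratified:
        sums = np.zeros((n_boot, k))
        sqs = np.zeros((n_boot, k))
        counts = np.broadcast_to(ns, (n_boot, k)).astype(float)
        for g, a in enumerate(arrs):
            idx = rng.integers(0, a.size, size=(n_boot, a.size))
            draw = a[idx]
            sums[:, g] = draw.sum(axis=1)
            sqs[:, g] = (draw**2).sum(axis=1)
    else:
        pooled = np.concatenate(arrs)
        labels = np.repeat(np.arange(k), ns)
        sums = np.zeros((n_boot, k))
        sqs = np.zeros((n_boot, k))
        counts = np.zeros((n_boot, k))
        for rep in range(n_boot):
            while True:
                idx = rng.integers(0, N, size=N)
                lab = labels[idx]
                cts = np.bincount(lab, minlength=k)
                if (cts >= 2).all():
                    break
            draw = pooled[idx]
            counts[rep] = cts
            for g in range(k):
                sel = draw[lab == g]
                sums[rep, g] = sel.sum()
                sqs[rep, g] = (sel**2).sum()

    tot = counts.sum(axis=1)
    means = sums / counts
    grand = sums.sum(axis=1) / tot
    ss_b = (counts * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_w = (sqs - counts * means**2).sum(axis=1)
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (tot - k)
    n0 = (tot - (counts**2).sum(axis=1) / tot) / (k - 1)
    s2_b = np.maximum((ms_b - ms_w) / n0, 0.0)
    return s2_b, ms_w


def pst_bootstrap(
    values,
    groups,
    c_over_h2: float = 1.0,
    n_boot: int = 1000,
    confidence: float = 0.99,
    seed: int | None = None,
    stratified: bool = True,
) -> tuple[float, float, float]:
    """Pst point estimate with a percentile bootstrap CI at one c/h^2.

    Returns ``(estimate, ci_low, ci_high)``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    arrs = _group_arrays(values, groups)
    estimate = pst(_components_from_groups(arrs), c_over_h2)
    rng = np.random.default_rng(seed)
    s2_b, s2_w = _bootstrap_components(arrs, n_boot, rng, stratified=stratified)
    num = c_over_h2 * s2_b
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = np.where(num + 2.0 * s2_w > 0, num / (num + 2.0 * s2_w), 0.0)
    alpha = (1.0 - confidence) / 2.0
    return (
        float(estimate),
        float(np.quantile(boot, alpha)),
        float(np.quantile(boot, 1.0 - alpha)),
    )


def pst_scan(
    values,
    groups,
    trait: str = "trait",
    grid_min: float = 0.0,
    grid_max: float = 2.0,
    grid_step: float = 0.05,
    n_boot: int = 1000,
    confidence: float = 0.99,
    seed: int | None = None,
    stratified: bool = True,
) -> PstCurve:
    """Pst over an inclusive c/h^2 grid with a shared bootstrap replicate set.

    Point estimates come from the full-data variance components; a single
    set of bootstrap component estimates is re-evaluated at every grid value
    (c/h^2 is a deterministic transform of the components, so re-resampling
    per grid point would add only noise).
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    arrs = _group_arrays(values, groups)
    vc = _components_from_groups(arrs)
    n_steps = int(round((grid_max - grid_min) / grid_step))
    grid = grid_min + grid_step * np.arange(n_steps + 1)
    point = np.array([pst(vc, x) for x in grid])

    rng = np.random.default_rng(seed)
    s2_b, s2_w = _bootstrap_components(arrs, n_boot, rng, stratified=stratified)
    num = grid[:, None] * s2_b[None, :]          # (grid, n_boot)
    den = num + 2.0 * s2_w[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = np.where(den > 0, num / den, 0.0)
    alpha = (1.0 - confidence) / 2.0
    ci_low = np.quantile(boot, alpha, axis=1)
    ci_high = np.quantile(boot, 1.0 - alpha, axis=1)
    return PstCurve(
        trait=trait, grid=grid, pst=point,
        ci_low=np.minimum(ci_low, point), ci_high=np.maximum(ci_high, point),
        n_boot=n_boot, confidence=confidence, seed=seed,
    )


def drift_assessment(curve: PstCurve, fst: FstResult, threshold: float = 0.5) -> DriftVerdict:
    """Apply the CI-overlap criterion: drift is rejected as the sole driver
    when the Pst lower CI exceeds the Fst upper CI at some c/h^2 at or below
    ``threshold``."""
    above = curve.ci_low > fst.ci_high
    if above.any():
        critical = float(curve.grid[int(np.argmax(above))])
        excluded = critical <= threshold
    else:
        critical, excluded = None, False
    return DriftVerdict(trait=curve.trait, critical_c_over_h2=critical,
                        drift_excluded=excluded, threshold=threshold)
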