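"""Synthetic genotype, trait and landscape generators with known truth.

Genotypes follow the Balding-Nichols model: each locus draws an ancestral
frequency p, each population a frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
(mean p, variance p(1-p)F), and each individual a Binomial(2, .) genotype,
so the expected Fst equals the dispersal parameter F.  Traits follow a
one-way random-effects model, value = mu + b_pop + e_ind with Normal
components, giving a closed-form theoretical Pst at any c/h^2.  Landscapes
place populations uniformly in a square with elevations drawn independently
of position, so geographic and elevational distances do not covary by
construction.

Default dimensions (12 populations x 20 individuals, 654 unlinked biallelic
SNPs at F = 0.05, 24 raw traits, ~300 km extent, elevations 39-1874 m)
emulate a low-differentiation plant system sampled along an elevational
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, SiteTable, TraitTable, ValidationError

__all__ = [
    "simulate_genotypes",
    "simulate_traits",
    "simulate_landscape",
    "make_study_fixture",
    "SimulationTruth",
    "StudyFixture",
    "STUDY_LATITUDE",
]

#: Latitude (deg N) at which km are converted to degrees of longitude.
STUDY_LATITUDE = 43.0

_KM_PER_DEG = 6371.0088 * np.pi / 180.0

#: 24 raw trait names of a Dianthus-style morphometric protocol, in
#: measurement-protocol order (IDs 1..24 follow this order).
TRAIT_NAMES = [
    "plant_height", "n_internodes", "lower_internode_length",
    "upper_internode_length", "basal_leaf_length", "basal_leaf_width",
    "upper_stem_leaf_length", "upper_stem_leaf_width",
    "lower_stem_leaf_length", "lower_stem_leaf_width", "n_flowers_per_stem",
    "n_epicalyx_scales", "upper_epicalyx_scale_length",
    "upper_epicalyx_scale_mucro_length", "upper_epicalyx_scale_width",
    "calyx_length", "calyx_width", "calyx_teeth_length", "corolla_diameter",
    "petal_length", "petal_limb_length", "petal_limb_width", "ovary_length",
    "anther_length",
]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, for recovery testing."""

    seed: int | None = None
    fst_true: float | None = None
    sigma2_B_true: float | None = None
    sigma2_W_true: float | None = None
    c_true: float | None = None
    h2_true: float | None = None
    pst_theoretical: float | None = None  # at ratio c_true/h2_true
    ibd_length_scale_km: float | None = None
    # realized (finite-sample) components of the drawn effects; the natural
    # referent for conditional (within-population bootstrap) inference
    sigma2_B_realized: float | None = None
    sigma2_W_realized: float | None = None

    def pst_at(self, c_over_h2: float) -> float:
        """Theoretical Pst of the simulated trait at any c/h^2."""
        num = c_over_h2 * self.sigma2_B_true
        return num / (num + 2.0 * self.sigma2_W_true)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def simulate_genotypes(
    n_pops: int = 12,
    n_per_pop: int = 20,
    n_loci: int = 654,
    fst_true: float = 0.05,
    p_anc_range: tuple[float, float] = (0.1, 0.9),
    seed: int | None = None,
    missing_rate: float = 0.0,
    sites: SiteTable | None = None,
    ibd_length_scale_km: float | None = None,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Balding-Nichols genotypes for ``n_pops`` populations.

    With ``sites`` and ``ibd_length_scale_km`` given, population allele
    frequencies are spatially autocorrelated (Gaussian field with covariance
    exp(-d/length_scale) matched to the Balding-Nichols variance), producing
    an isolation-by-distance pattern while keeping E(Fst) near ``fst_true``.
    """
    if not 0.0 < fst_true < 1.0:
        raise ValidationError("fst_true must be in (0, 1)")
    if n_per_pop < 2:
        raise ValidationError("need at least 2 individuals per population")
    lo, hi = p_anc_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValidationError("p_anc_range must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    F = fst_true
    p_anc = rng.uniform(lo, hi, size=n_loci)

    if ibd_length_scale_km is not None:
        if sites is None:
            raise ValidationError("isolation-by-distance mode needs a SiteTable")
        from .spatial import geographic_distance_matrix

        d = geographic_distance_matrix(sites).values
        cov = np.exp(-d / ibd_length_scale_km)
        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(n_pops))
        z = chol @ rng.standard_normal((n_pops, n_loci))
        sd = np.sqrt(F * p_anc * (1.0 - p_anc))
        p_pop = np.clip(p_anc[None, :] + sd[None, :] * z, 1e-6, 1.0 - 1e-6)
    else:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        if (a <= 0).any() or (b <= 0).any():
            raise ValidationError("degenerate Beta parameters for population frequencies")
        p_pop = rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))

    dosages = rng.binomial(2, np.repeat(p_pop, n_per_pop, axis=0)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = MISSING
    pops = (sites.populations if sites is not None
            else [f"P{i + 1:02d}" for i in range(n_pops)])
    samples = [f"{pops[i]}_{j + 1:02d}" for i in range(n_pops) for j in range(n_per_pop)]
    g = GenotypeMatrix(
        samples=samples,
        populations=[pops[i] for i in range(n_pops) for _ in range(n_per_pop)],
        dosages=dosages,
        loci=[f"contig{j + 1}:101" for j in range(n_loci)],
    )
    truth = SimulationTruth(seed=seed, fst_true=F, ibd_length_scale_km=ibd_length_scale_km)
    return g, truth


def simulate_traits(
    n_pops: int = 12,
    n_per_pop: int = 20,
    mu: float = 50.0,
    sigma2_B: float = 7.0,
    sigma2_W: float = 2.0,
    c: float = 1.0,
    h2: float = 1.0,
    seed: int | None = None,
    trait: str = "trait",
    populations: list[str] | None = None,
) -> tuple[TraitTable, SimulationTruth]:
    """One-way random-effects trait: value = mu + b_pop + e_ind.

    ``mu`` should be large relative to the component scales so measurements
    stay non-negative (the containers enforce non-negativity).
    """
    if sigma2_B < 0 or sigma2_W < 0 or (sigma2_B == 0 and sigma2_W == 0):
        raise ValidationError("variance components must be >= 0 and not both zero")
    rng = np.random.default_rng(seed)
    pops = populations or [f"P{i + 1:02d}" for i in range(n_pops)]
    b = rng.normal(0.0, np.sqrt(sigma2_B), size=n_pops)
    e = rng.normal(0.0, np.sqrt(sigma2_W), size=(n_pops, n_per_pop))
    values = np.clip(mu + b[:, None] + e, 0.0, None).ravel()
    samples = [f"{pops[i]}_{j + 1:02d}" for i in range(n_pops) for j in range(n_per_pop)]
    table = TraitTable(
        samples=samples,
        populations=[pops[i] for i in range(n_pops) for _ in range(n_per_pop)],
        data=pd.DataFrame({trait: values}),
    )
    ratio = c / h2
    truth = SimulationTruth(
        seed=seed, sigma2_B_true=sigma2_B, sigma2_W_true=sigma2_W,
        c_true=c, h2_true=h2,
        pst_theoretical=ratio * sigma2_B / (ratio * sigma2_B + 2.0 * sigma2_W),
        sigma2_B_realized=float(np.var(b, ddof=1)) if n_pops > 1 else 0.0,
        sigma2_W_realized=float(np.mean(np.var(e, axis=1, ddof=1))),
    )
    return table, truth


def simulate_landscape(
    n_pops: int = 12,
    extent_km: float = 300.0,
    elev_range_m: tuple[float, float] = (39.0, 1874.0),
    decouple_elevation: bool = True,
    seed: int | None = None,
) -> SiteTable:
    """Populations scattered uniformly in a square landscape.

    With ``decouple_elevation`` (default) elevations are drawn independently
    of position, so elevational and geographic distances do not covary;
    otherwise elevation increases linearly eastward with mild noise.
    """
    if n_pops < 4:
        raise ValidationError("need at least 4 populations")
    rng = np.random.default_rng(seed)
    if extent_km == 0:
        import warnings

        warnings.warn("extent_km = 0: all geographic distances degenerate to zero")
    x = rng.uniform(0.0, extent_km, size=n_pops)  # eastward km
    y = rng.uniform(0.0, extent_km, size=n_pops)  # northward km
    lat = STUDY_LATITUDE + y / _KM_PER_DEG
    lon = 10.0 + x / (_KM_PER_DEG * np.cos(np.radians(STUDY_LATITUDE)))
    lo, hi = elev_range_m
    if decouple_elevation or extent_km == 0:
        elev = rng.uniform(lo, hi, size=n_pops)
    else:
        frac = np.clip(x / max(extent_km, 1e-9) + rng.normal(0, 0.1, n_pops), 0, 1)
        elev = lo + frac * (hi - lo)
    return SiteTable(pd.DataFrame(
        {"latitude": lat, "longitude": lon, "elevation": elev},
        index=pd.Index([f"P{i + 1:02d}" for i in range(n_pops)], name="population"),
    ))


@dataclass
class StudyFixture:
    """End-to-end synthetic bundle mirroring the study's dimensions."""

    genotypes: GenotypeMatrix
    traits: TraitTable
    sites: SiteTable
    truth: SimulationTruth
    selected_traits: list[str] = field(default_factory=list)   # high theoretical Pst
    null_traits: list[str] = field(default_factory=list)       # no among-population signal
    redundant_traits: list[str] = field(default_factory=list)  # near-duplicates (|r| > 0.8)


def make_study_fixture(seed: int | None = None, ibd: bool = False) -> StudyFixture:
    """Full synthetic study: genotypes, 24 traits, landscape, known truth.

    Three focal traits carry strong between-population signal (theoretical
    Pst ~ 0.93 at c/h^2 = 1) with population means negatively tied to
    elevation; two traits carry no among-population signal (to be dropped by
    refinement); four traits are noisy near-duplicates of others (to be
    pruned at |r| > 0.8); the remainder carry moderate independent signal.
    Genotypes are simulated at F = 0.05 with 4% missing calls.  With
    ``ibd=True`` allele frequencies decay with distance, adding an
    isolation-by-distance pattern.
    """
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    n_pops, n_per_pop = 12, 20
    sites = simulate_landscape(n_pops=n_pops, seed=child())
    genotypes, truth = simulate_genotypes(
        n_pops=n_pops, n_per_pop=n_per_pop, n_loci=654, fst_true=0.05,
        seed=child(), missing_rate=0.04, sites=sites,
        ibd_length_scale_km=100.0 if ibd else None,
    )

    selected = ["plant_height", "basal_leaf_width", "calyx_length"]
    null_traits = ["upper_epicalyx_scale_mucro_length", "lower_internode_length"]
    redundant = {
        "lower_stem_leaf_width": "basal_leaf_width",
        "basal_leaf_length": "basal_leaf_width",
        "petal_limb_length": "petal_length",
        "upper_internode_length": "plant_height",
    }

    elev = sites.data["elevation"].to_numpy()
    z_elev = (elev - elev.mean()) / elev.std(ddof=0)

    # Strong signal: sigma2_B/(sigma2_B + 2 sigma2_W) ~ 0.93 at c/h^2 = 1.
    sigma2_W_sel, pst_target = 2.0, 0.93
    sigma2_B_sel = 2.0 * sigma2_W_sel * pst_target / (1.0 - pst_target)
    rho_elev = 0.85  # share of between-population sd tied to elevation

    columns: dict[str, np.ndarray] = {}
    pops = sites.populations
    for name in TRAIT_NAMES:
        if name in selected:
            s2b, s2w, mu = sigma2_B_sel, sigma2_W_sel, 60.0
            b = np.sqrt(s2b) * (-rho_elev * z_elev
                                + np.sqrt(1 - rho_elev**2) * rng.standard_normal(n_pops))
        elif name in null_traits:
            s2b, s2w, mu = 0.0, 2.0, 30.0
            b = np.zeros(n_pops)
        elif name in redundant:
            continue  # filled after their sources
        else:
            s2b, s2w, mu = 1.0, 2.0, 40.0
            b = np.sqrt(s2b) * rng.standard_normal(n_pops)
        e = np.sqrt(s2w) * rng.standard_normal((n_pops, n_per_pop))
        columns[name] = np.clip(mu + b[:, None] + e, 0.0, None).ravel()
    for name, source in redundant.items():
        noise = 0.2 * rng.standard_normal(columns[source].shape)
        columns[name] = np.clip(0.8 * columns[source] + 5.0 + noise, 0.0, None)

    samples = [f"{pops[i]}_{j + 1:02d}" for i in range(n_pops) for j in range(n_per_pop)]
    traits = TraitTable(
        samples=samples,
        populations=[pops[i] for i in range(n_pops) for _ in range(n_per_pop)],
        data=pd.DataFrame({n: columns[n] for n in TRAIT_NAMES}),
    )
    truth.sigma2_B_true = sigma2_B_sel
    truth.sigma2_W_true = sigma2_W_sel
    truth.c_true = truth.h2_true = 1.0
    truth.pst_theoretical = pst_target
    truth.seed = seed
    return StudyFixture(
        genotypes=genotypes, traits=traits, sites=sites, truth=truth,
        selected_traits=selected, null_traits=null_traits,
        redundant_traits=list(redundant),
    )
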