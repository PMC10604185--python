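"""Distance matrices (great-circle km, elevational m, morphometric
Euclidean) and the Mantel permutation test of matrix association."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .traits import RefinedTraitSet
from .types import SiteTable, SymmetricMatrix, ValidationError

__all__ = [
    "EARTH_RADIUS_KM",
    "geographic_distance_matrix",
    "elevation_distance_matrix",
    "morphometric_distance_matrix",
    "mantel_test",
    "MantelResult",
]

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

#: Below this many populations the Mantel null is enumerated exactly.
_EXACT_ENUMERATION_MAX_N = 7


def geographic_distance_matrix(s: SiteTable) -> SymmetricMatrix:
    """Great-circle (haversine) distances between population sites, in km."""
    if len(s.populations) < 2:
        raise ValidationError("need at least 2 populations")
    lat = np.radians(s.data["latitude"].to_numpy(float))
    lon = np.radians(s.data["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float jitter
    return SymmetricMatrix(labels=s.populations, values=d, kind="geographic_km")


def elevation_distance_matrix(s: SiteTable) -> SymmetricMatrix:
    """Absolute elevation differences between populations, in metres."""
    e = s.data["elevation"].to_numpy(float)
    d = np.abs(e[:, None] - e[None, :])
    return SymmetricMatrix(labels=s.populations, values=d, kind="elevational_m")


def morphometric_distance_matrix(r: RefinedTraitSet | pd.DataFrame) -> SymmetricMatrix:
    """Euclidean distances between population rows of the z-scored means."""
    z = r.pop_means_z if isinstance(r, RefinedTraitSet) else r
    d = squareform(pdist(z.to_numpy(float), metric="euclidean"))
    return SymmetricMatrix(labels=list(z.index), values=d, kind="morphometric_euclidean")


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None
    tail: str = "greater"
    method: str = "sampled"  # "sampled" or "exact"

    def to_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n_perm": self.n_perm,
                "seed": self.seed, "tail": self.tail, "method": self.method}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValidationError("zero variance in off-diagonal distances")
    return (v - v.mean()) / sd


def mantel_test(
    a: SymmetricMatrix,
    b: SymmetricMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel test of association between two matrices.

    ``r`` is the Pearson correlation of the lower-triangle off-diagonal
    entries; the null is built by jointly permuting rows and columns of the
    second matrix.  For up to 7 populations all relabelings are enumerated
    exactly; otherwise ``n_perm`` random permutations are drawn and
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if a.labels != b.labels:
        raise ValidationError(f"label mismatch between matrices: {a.labels} vs {b.labels}")
    n = a.n
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 populations")
    tri = np.tril_indices(n, k=-1)
    va = _standardize(a.values[tri])
    B = b.values
    vb = _standardize(B[tri])
    m = va.size
    r_obs = float(va @ vb / m)

    eps = 1e-12
    if n <= _EXACT_ENUMERATION_MAX_N:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p_arr = np.array(perm)
            vp = _standardize(B[np.ix_(p_arr, p_arr)][tri])
            count += float(va @ vp / m) >= r_obs - eps
            total += 1
        return MantelResult(r=r_obs, p_value=count / total, n_perm=total,
                           seed=seed, method="exact")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p_arr = rng.permutation(n)
        vp = _standardize(B[np.ix_(p_arr, p_arr)][tri])
        count += float(va @ vp / m) >= r_obs - eps
    return MantelResult(r=r_obs, p_value=(count + 1) / (n_perm + 1), n_perm=n_perm,
                       seed=seed, method="sampled")
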