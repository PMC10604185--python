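"""Core containers shared by every analysis stage.

All containers are thin, validated wrappers around numpy arrays and pandas
objects.  They exist to make the contracts between stages explicit: a
:class:`GenotypeMatrix` is always biallelic dosages with one population label
per sample, a :class:`SymmetricMatrix` is always square, symmetric and
labelled, and so on.  Validation happens at construction so downstream code
can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype in a dosage matrix.
MISSING: int = -1

#: Allowed kinds of a labelled symmetric matrix.
MATRIX_KINDS = ("genetic_fst", "geographic_km", "elevational_m", "morphometric_euclidean")

#: Kinds that are true distances: zero diagonal, non-negative entries.
_DISTANCE_KINDS = ("geographic_km", "elevational_m", "morphometric_euclidean")


class ValidationError(ValueError):
    """Raised when an input container violates one of its invariants."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-allele dosage matrix with population labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers, one per row of ``dosages``.
    populations
        Population label of each sample (parallel to ``samples``).
    dosages
        ``(n_samples, n_loci)`` integer array with values in ``{0, 1, 2}``
        or :data:`MISSING` for uncalled genotypes.
    loci
        Locus identifiers (``contig:position``), one per column.
    """

    samples: list[str]
    populations: list[str]
    dosages: np.ndarray
    loci: list[str]

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.populations = list(self.populations)
        self.loci = list(self.loci)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(self.samples) != len(self.populations):
            raise ValidationError("one population label required per sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} at sample {self.samples[i]}, "
                f"locus {self.loci[j]} outside {{0,1,2,missing}}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Row indices of every population, in label order."""
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.population_labels}

    def reorder_samples(self, order: Sequence[int]) -> "GenotypeMatrix":
        order = list(order)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in order],
            populations=[self.populations[i] for i in order],
            dosages=self.dosages[order],
            loci=self.loci,
        )


@dataclass
class TraitTable:
    """Individuals x traits measurement table with population labels.

    ``data`` is a float DataFrame indexed by sample identifier, one column
    per trait; missing measurements are ``NaN``.  Measurements are
    non-negative (lengths, widths, counts).
    """

    samples: list[str]
    populations: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.populations = list(self.populations)
        if len(self.samples) != len(self.populations):
            raise ValidationError("one population label required per sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValidationError("trait names must be unique")
        self.data = self.data.astype(float)
        self.data.index = pd.Index(self.samples, name="sample")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("trait measurements must be non-negative")

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)


@dataclass
class SiteTable:
    """One row per population: WGS84 coordinates and elevation (m a.s.l.)."""

    data: pd.DataFrame  # index: population; columns: latitude, longitude, elevation

    def __post_init__(self) -> None:
        required = {"latitude", "longitude", "elevation"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"site table missing columns: {sorted(missing)}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicated population labels: {dups}")
        self.data = self.data[["latitude", "longitude", "elevation"]].astype(float)
        lat, lon, ele = (self.data[c] for c in ("latitude", "longitude", "elevation"))
        if ((lat < -90) | (lat > 90)).any():
            bad = self.data.index[(lat < -90) | (lat > 90)].tolist()
            raise ValidationError(f"latitude outside [-90, 90] for: {bad}")
        if ((lon < -180) | (lon > 180)).any():
            bad = self.data.index[(lon < -180) | (lon > 180)].tolist()
            raise ValidationError(f"longitude outside [-180, 180] for: {bad}")
        if (~np.isfinite(ele)).any():
            bad = self.data.index[~np.isfinite(ele)].tolist()
            raise ValidationError(f"non-finite elevation for: {bad}")

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    def subset(self, populations: Sequence[str]) -> "SiteTable":
        return SiteTable(self.data.loc[list(populations)].copy())


@dataclass
class SymmetricMatrix:
    """Labelled square symmetric matrix (Fst, km, metres, trait distance)."""

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal must be zero")
        if self.kind in _DISTANCE_KINDS and (self.values < 0).any():
            raise ValidationError(f"{self.kind} entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle off-diagonal entries, row-major order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: Sequence[str]) -> "SymmetricMatrix":
        idx = [self.labels.index(l) for l in labels]
        return SymmetricMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)
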