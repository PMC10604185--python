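"""Orchestration of the full analysis from a single configuration.

Stages run in dependency order: read inputs -> Fst (pairwise + global CI) ->
trait refinement -> PCA -> elevation associations -> distance matrices ->
Mantel battery -> Pst scans -> drift verdicts.  All stochastic stages draw
their seeds from one master seed via a stable hash fan-out, so a fixed
configuration reproduces bit-identical numbers and each stage, run alone
with its derived seed, matches the orchestrated run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .fst import FstResult, global_fst_ci
from .pst import DriftVerdict, PstCurve, drift_assessment, pst_scan
from .spatial import (
    MantelResult,
    elevation_distance_matrix,
    geographic_distance_matrix,
    mantel_test,
    morphometric_distance_matrix,
)
from .traits import (
    ElevationAssociation,
    PCAResult,
    RefinedTraitSet,
    elevation_association,
    pca_population_means,
    refine_traits,
)
from .types import SymmetricMatrix, ValidationError

__all__ = ["run_full_analysis", "stage_seed", "AnalysisReport", "StageError",
           "DEFAULT_CONFIG", "load_config"]

#: The six matrix associations tested by default.
MANTEL_BATTERY = [
    ("GEN", "GEO"), ("GEN", "ELE"), ("MOR", "GEO"),
    ("MOR", "ELE"), ("MOR", "GEN"), ("ELE", "GEO"),
]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "fst": {"n_boot": 1000, "confidence": 0.99},
    "refine": {"alpha_levene": 0.05, "alpha_test": 0.01, "r_max": 0.8},
    "mantel": {"n_perm": 9999, "alpha": 0.01},
    "pst": {"traits": "auto", "n_traits_auto": 3, "grid": [0.0, 2.0, 0.05],
            "n_boot": 1000, "confidence": 0.99, "threshold": 0.5,
            "stratified": True},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable across runs)."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


@dataclass
class AnalysisReport:
    fst: FstResult
    mantel: dict[str, MantelResult]
    refinement: RefinedTraitSet
    pca: PCAResult
    elevation: list[ElevationAssociation]
    pst_curves: dict[str, PstCurve]
    verdicts: dict[str, DriftVerdict]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fst": self.fst.to_dict(),
            "pairwise_fst": {
                "labels": self.fst.pairwise.labels,
                "values": self.fst.pairwise.values.tolist(),
            },
            "mantel": {k: v.to_dict() for k, v in self.mantel.items()},
            "refinement": self.refinement.summary_dict(),
            "pca": {
                "explained": self.pca.explained.tolist(),
                "scores": self.pca.scores.to_dict(orient="index"),
                "loadings": self.pca.loadings.to_dict(orient="index"),
            },
            "elevation": [
                {"trait": e.trait, "rho": e.rho, "p_value": e.p_value,
                 "fit_degree": e.fit_degree, "adj_r2": e.adj_r2,
                 "F_stat": e.F_stat, "fit_p": e.fit_p}
                for e in self.elevation
            ],
            "pst": {
                t: {"grid": c.grid.tolist(), "pst": c.pst.tolist(),
                    "ci_low": c.ci_low.tolist(), "ci_high": c.ci_high.tolist(),
                    "n_boot": c.n_boot, "confidence": c.confidence}
                for t, c in self.pst_curves.items()
            },
            "verdicts": {t: v.to_dict() for t, v in self.verdicts.items()},
            "provenance": self.provenance,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_full_analysis(config: dict, out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute every stage of the analysis from one configuration.

    ``config`` must contain an ``inputs`` section naming ``vcf``, ``popmap``,
    ``traits`` and ``sites`` paths; other sections override
    :data:`DEFAULT_CONFIG`.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    inputs = cfg.get("inputs") or {}
    for key in ("vcf", "popmap", "traits", "sites"):
        if key not in inputs:
            raise StageError(f"stage inputs: configuration is missing inputs.{key}")
        if not Path(inputs[key]).exists():
            raise StageError(f"stage inputs: path does not exist: {inputs[key]}")
    master = int(cfg["seed"])

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name}: {exc}") from exc

    genotypes = _stage("read", pio.read_genotypes, inputs["vcf"], inputs["popmap"])
    trait_table = _stage("read", pio.read_traits, inputs["traits"],
                         na_string=cfg.get("na_string", "NA"))
    sites = _stage("read", pio.read_sites, inputs["sites"])

    pop_order = sites.populations
    for name, got in (("genotypes", set(genotypes.populations)),
                      ("traits", set(trait_table.populations))):
        if got != set(pop_order):
            raise StageError(
                f"stage read: population labels in {name} do not match site table; "
                f"only in {name}: {sorted(got - set(pop_order))}, "
                f"missing from {name}: {sorted(set(pop_order) - got)}"
            )

    fst_res = _stage("fst", global_fst_ci, genotypes,
                     n_boot=cfg["fst"]["n_boot"], confidence=cfg["fst"]["confidence"],
                     seed=stage_seed(master, "fst"))
    fst_res.pairwise = fst_res.pairwise.reorder(pop_order)

    refined = _stage("refine", refine_traits, trait_table,
                     alpha_levene=cfg["refine"]["alpha_levene"],
                     alpha_test=cfg["refine"]["alpha_test"],
                     r_max=cfg["refine"]["r_max"])
    # align population order with the site table everywhere downstream
    refined.pop_means = refined.pop_means.loc[pop_order]
    refined.pop_means_z = refined.pop_means_z.loc[pop_order]
    refined.populations = pop_order

    pca = _stage("pca", pca_population_means, refined)
    elevations = [
        _stage("elevation", elevation_association, refined, sites, trait)
        for trait in refined.retained_traits
    ]

    matrices: dict[str, SymmetricMatrix] = {
        "GEN": fst_res.pairwise,
        "GEO": _stage("distances", geographic_distance_matrix, sites),
        "ELE": _stage("distances", elevation_distance_matrix, sites),
        "MOR": _stage("distances", morphometric_distance_matrix, refined),
    }
    mantel: dict[str, MantelResult] = {}
    for x, y in MANTEL_BATTERY + [tuple(e) for e in cfg["mantel"].get("extra", [])]:
        key = f"{x}~{y}"
        mantel[key] = _stage("mantel", mantel_test, matrices[x], matrices[y],
                             n_perm=cfg["mantel"]["n_perm"],
                             seed=stage_seed(master, f"mantel:{key}"))

    pst_cfg = cfg["pst"]
    if pst_cfg["traits"] == "auto":
        ranked = sorted(elevations, key=lambda e: (e.p_value, -abs(e.rho), e.trait))
        pst_traits = [e.trait for e in ranked[: int(pst_cfg["n_traits_auto"])]]
    else:
        pst_traits = list(pst_cfg["traits"])
    gmin, gmax, gstep = pst_cfg["grid"]

    complete = ~trait_table.data.isna().any(axis=1).to_numpy()
    pops = np.asarray(trait_table.populations)[complete]
    curves: dict[str, PstCurve] = {}
    verdicts: dict[str, DriftVerdict] = {}
    for trait in pst_traits:
        if trait not in trait_table.traits:
            raise StageError(f"stage pst: trait {trait!r} not in the trait table")
        values = trait_table.data.loc[complete, trait].to_numpy()
        curve = _stage("pst", pst_scan, values, pops, trait=trait,
                       grid_min=gmin, grid_max=gmax, grid_step=gstep,
                       n_boot=pst_cfg["n_boot"], confidence=pst_cfg["confidence"],
                       seed=stage_seed(master, f"pst:{trait}"),
                       stratified=pst_cfg["stratified"])
        curves[trait] = curve
        verdicts[trait] = _stage("pst", drift_assessment, curve, fst_res,
                                 threshold=pst_cfg["threshold"])

    try:
        pkg_version = version("pstfst")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    report = AnalysisReport(
        fst=fst_res, mantel=mantel, refinement=refined, pca=pca,
        elevation=elevations, pst_curves=curves, verdicts=verdicts,
        provenance={
            "config_hash": _config_hash(cfg),
            "seed": master,
            "stage_seeds": {
                "fst": stage_seed(master, "fst"),
                **{f"mantel:{k}": stage_seed(master, f"mantel:{k}") for k in mantel},
                **{f"pst:{t}": stage_seed(master, f"pst:{t}") for t in curves},
            },
            "version": pkg_version,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if out_dir is not None:
        _write_outputs(report, matrices, Path(out_dir))
    return report


def _write_outputs(report: AnalysisReport, matrices: dict[str, SymmetricMatrix],
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, name in (("GEN", "pairwise_fst"), ("GEO", "geographic_km"),
                      ("ELE", "elevational_m"), ("MOR", "morphometric_euclidean")):
        pio.write_symmetric_matrix(matrices[key], out_dir / f"{name}.tsv")
    report.refinement.pop_means_z.to_csv(out_dir / "pop_means_z.tsv", sep="\t",
                                         float_format="%.10g")
    report.pca.scores.to_csv(out_dir / "pca_scores.tsv", sep="\t", float_format="%.10g")
    report.pca.loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame({"component": report.pca.scores.columns,
                  "explained": report.pca.explained}).to_csv(
        out_dir / "pca_explained.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame([{
        "trait": e.trait, "rho": e.rho, "p_value": e.p_value,
        "adj_r2": e.adj_r2, "F_stat": e.F_stat, "fit_p": e.fit_p,
    } for e in report.elevation]).to_csv(out_dir / "elevation_association.tsv",
                                         sep="\t", index=False, float_format="%.10g")
    for pair, res in report.mantel.items():
        x, y = pair.split("~")
        scatter = pd.DataFrame({x: matrices[x].condensed(), y: matrices[y].condensed()})
        scatter.to_csv(out_dir / f"mantel_{x}_{y}_scatter.tsv", sep="\t",
                       index=False, float_format="%.10g")
    for trait, curve in report.pst_curves.items():
        curve.to_frame().to_csv(out_dir / f"pst_{trait}.tsv", sep="\t",
                                index=False, float_format="%.10g")
    report.write(out_dir / "report.json")
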