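"""End-to-end orchestration of the comparative pan-genomics analysis.

A single validated configuration drives the whole run: obtain a
presence/absence matrix (simulated with planted truth, or loaded from
files), partition it, build rarefaction curves and the openness fit,
test environment association, score COG enrichment for each associated
direction, profile KEGG-module completeness and cluster the profiles.
All randomness flows from one root seed, split deterministically per
stage, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .association import association_frame, environment_association
from .enrichment import category_enrichment, enrichment_frame
from .io import Environment
from .kegg import completeness_matrix, profile_distance, upgma
from .pangenome import curve_frame, fit_pan_curve, partition, rarefaction_curves
from .simulate import (
    SyntheticPangenomeSpec,
    assign_module_kos,
    default_module_plan,
    simulate_pangenome,
)

logger = logging.getLogger("pankit")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


def _version() -> str:
    try:
        return _pkg_version("pankit")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Either ``simulate = True`` (a synthetic dataset is generated from
    the seed) or the four input paths must point at existing files.
    """

    outdir: str
    seed: int
    simulate: bool = True
    matrix_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    module_path: str | None = None
    # synthetic design (used when simulate is True)
    n_genomes: int = 16
    n_htv: int = 2
    n_core: int = 800
    n_accessory: int = 2800
    unique_rate: float = 250.0
    n_planted_htv: int = 57
    n_planted_nonhtv: int = 82
    # analysis thresholds
    alpha: float = 0.05
    n_permutations: int = 20

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not self.simulate:
            for name in ("matrix_path", "annotation_path", "metadata_path", "module_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"simulate is false but {name} is not set")
                if not Path(path).exists():
                    raise ConfigError(f"{name}: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        return config

    def content_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.content_hash(), seed=config.seed, version=_version()
    )
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(config.seed).spawn(4)]

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        spec = SyntheticPangenomeSpec(
            n_genomes=config.n_genomes,
            n_htv=config.n_htv,
            n_core=config.n_core,
            n_accessory=config.n_accessory,
            unique_rate=config.unique_rate,
            n_planted_htv=config.n_planted_htv,
            n_planted_nonhtv=config.n_planted_nonhtv,
            seed=seeds[0],
        )
        matrix, annotation, metadata, truth = simulate_pangenome(spec)
        modules = default_module_plan()
        genome_kos = assign_module_kos(modules, metadata, seed=seeds[1])
        pio.write_matrix(matrix, outdir / "presence_matrix.tsv")
        pio.write_annotation_table(annotation, outdir / "annotation.tsv")
        pio.write_metadata_table(metadata, outdir / "metadata.tsv")
        pio.write_module_table(modules, outdir / "modules.tsv")
    else:
        matrix = pio.read_presence_matrix(config.matrix_path)
        annotation, metadata, modules = pio.read_tables(
            config.annotation_path, config.metadata_path, config.module_path
        )
        genome_kos = annotation.by_genome_kos()
    logger.info(
        "stage=input clusters=%d genomes=%d", matrix.shape[0], matrix.shape[1]
    )

    # --- pan-genome -------------------------------------------------------
    part = partition(matrix)
    curve = rarefaction_curves(
        matrix, n_permutations=config.n_permutations, seed=seeds[2]
    )
    fit = fit_pan_curve(curve)
    curve_frame(curve).to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)
    (outdir / "power_law_fit.json").write_text(
        json.dumps({"A": fit.A, "b": fit.b, "rss": fit.rss, "open": fit.open}, indent=2)
    )
    report.stages["pangenome"] = {
        "n_clusters": part.n_total,
        "n_core": part.n_core,
        "n_accessory": part.n_accessory,
        "n_unique": part.n_unique,
        "power_law_A": fit.A,
        "power_law_b": fit.b,
        "open": fit.open,
    }
    if truth is not None:
        report.stages["pangenome"]["truth_matches"] = (
            part.n_core == len(truth.core)
        )
    logger.info(
        "stage=pangenome core=%d accessory=%d unique=%d b=%.4f",
        part.n_core, part.n_accessory, part.n_unique, fit.b,
    )

    # --- association ------------------------------------------------------
    assoc = environment_association(matrix, metadata, alpha=config.alpha)
    association_frame(assoc).to_csv(outdir / "association.tsv", sep="\t", index=False)
    htv_clusters = {r.cluster_id for r in assoc if r.direction == Environment.HTV}
    non_clusters = {r.cluster_id for r in assoc if r.direction == Environment.NONHTV}
    n_significant = sum(r.significant for r in assoc)
    assert n_significant == len(htv_clusters) + len(non_clusters)
    report.stages["association"] = {
        "n_tested": len(assoc),
        "n_significant": n_significant,
        "n_htv_direction": len(htv_clusters),
        "n_nonhtv_direction": len(non_clusters),
    }
    logger.info(
        "stage=association tested=%d significant=%d htv=%d nonhtv=%d",
        len(assoc), n_significant, len(htv_clusters), len(non_clusters),
    )

    # --- enrichment -------------------------------------------------------
    cluster_cogs: dict[str, frozenset[str]] = {}
    for row in annotation:
        cid = row.protein_id.split("|", 1)[1] if "|" in row.protein_id else row.protein_id
        cluster_cogs.setdefault(cid, frozenset())
        cluster_cogs[cid] = cluster_cogs[cid] | row.cog_letters
    background = [cluster_cogs.get(c, frozenset()) for c in matrix.index]
    report.stages["enrichment"] = {}
    for tag, focal_ids in (("htv", htv_clusters), ("nonhtv", non_clusters)):
        focal = [cluster_cogs.get(c, frozenset()) for c in sorted(focal_ids)]
        if not any(focal):
            report.stages["enrichment"][tag] = {"n_categories": 0, "significant": []}
            continue
        results = category_enrichment(focal, background)
        enrichment_frame(results).to_csv(
            outdir / f"enrichment_{tag}.tsv", sep="\t", index=False
        )
        report.stages["enrichment"][tag] = {
            "n_categories": len(results),
            "significant": sorted(r.category for r in results if r.significant),
        }
    logger.info("stage=enrichment groups=%d", len(report.stages["enrichment"]))

    # --- KEGG modules -----------------------------------------------------
    if modules and genome_kos:
        scores = completeness_matrix(genome_kos, modules)
        pio.write_matrix(scores, outdir / "module_scores.tsv")
        dist = profile_distance(scores)
        tree = upgma(dist)
        pio.write_newick(tree.newick(), outdir / "module_dendrogram.nwk")
        first_left, first_right, _ = tree.merges[0]
        report.stages["modules"] = {
            "n_modules": scores.shape[0],
            "n_genomes": scores.shape[1],
            "first_merge": sorted(first_left + first_right),
        }
        logger.info("stage=modules n_modules=%d", scores.shape[0])

    (outdir / "report.json").write_text(report.to_json())
    return report
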