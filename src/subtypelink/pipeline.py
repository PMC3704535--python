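"""Stage orchestration: preprocess -> ssgsea -> correlate -> phylogeny ->
gsea -> cluster-pathways, driven by one YAML config.

Each stage reads its inputs from the output directory written by the
previous stage, so running the stages one by one is byte-identical to
``run-all``. A run manifest records the stages executed, the seed, a hash
of the config and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError
from .io_formats import (
    ExpressionCohort,
    read_expression,
    read_gmt,
    read_labels,
    read_matrix,
    read_table,
    write_matrix,
    write_newick_file,
    write_table,
)
from . import correlation, gsea, pathway_clustering, phylogeny, preprocess, ssgsea

logger = logging.getLogger(__name__)

STAGES = [
    "preprocess", "ssgsea", "correlate", "phylogeny", "gsea",
    "cluster_pathways",
]


@dataclass
class CohortEntry:
    cohort_id: str
    path: str
    labels: str
    scale: str = "absolute"
    tissue: str = "unknown"
    probe_map: str | None = None


@dataclass
class RunConfig:
    cohorts: list[CohortEntry]
    gmt: str
    out_dir: str
    seed: int = 0
    min_common_genes: int = preprocess.DEFAULT_MIN_COMMON
    center: str = "median"
    ssgsea_alpha: float = ssgsea.DEFAULT_ALPHA
    ssgsea_min_set_size: int = ssgsea.DEFAULT_MIN_SET_SIZE
    ssgsea_input: str = "centered"  # "centered" | "raw"
    gsea_n_perm: int = gsea.DEFAULT_N_PERM
    gsea_weight_p: float = gsea.DEFAULT_WEIGHT_P
    gsea_q_threshold: float = gsea.DEFAULT_Q_THRESHOLD
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict, base: Path | None = None) -> "RunConfig":
        def _resolve(p: str) -> str:
            return str((base / p) if base and not Path(p).is_absolute() else p)

        for key in ("cohorts", "gmt", "out_dir"):
            if key not in cfg:
                raise ConfigError(f"config is missing required key {key!r}")
        entries = []
        for c in cfg["cohorts"]:
            for key in ("id", "path", "labels"):
                if key not in c:
                    raise ConfigError(
                        f"cohort entry is missing required key {key!r}"
                    )
            entries.append(
                CohortEntry(
                    cohort_id=c["id"],
                    path=_resolve(c["path"]),
                    labels=_resolve(c["labels"]),
                    scale=c.get("scale", "absolute"),
                    tissue=c.get("tissue", "unknown"),
                    probe_map=(
                        _resolve(c["probe_map"]) if c.get("probe_map") else None
                    ),
                )
            )
        s = cfg.get("ssgsea", {})
        g = cfg.get("gsea", {})
        return cls(
            cohorts=entries,
            gmt=_resolve(cfg["gmt"]),
            out_dir=_resolve(cfg["out_dir"]),
            seed=int(cfg.get("seed", 0)),
            min_common_genes=int(
                cfg.get("min_common_genes", preprocess.DEFAULT_MIN_COMMON)
            ),
            center=cfg.get("center", "median"),
            ssgsea_alpha=float(s.get("alpha", ssgsea.DEFAULT_ALPHA)),
            ssgsea_min_set_size=int(
                s.get("min_set_size", ssgsea.DEFAULT_MIN_SET_SIZE)
            ),
            ssgsea_input=s.get("input", "centered"),
            gsea_n_perm=int(g.get("n_perm", gsea.DEFAULT_N_PERM)),
            gsea_weight_p=float(g.get("weight_p", gsea.DEFAULT_WEIGHT_P)),
            gsea_q_threshold=float(
                g.get("q_threshold", gsea.DEFAULT_Q_THRESHOLD)
            ),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(cfg, base=path.parent)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _load_raw_cohorts(config: RunConfig) -> list[ExpressionCohort]:
    cohorts = []
    for entry in config.cohorts:
        cohort = read_expression(
            entry.path, labels=entry.labels, scale=entry.scale,
            cohort_id=entry.cohort_id,
        )
        if entry.probe_map is not None:
            pm = dict(
                read_table(entry.probe_map).itertuples(index=False, name=None)
            )
            merged = preprocess.merge_probes_by_gene(cohort.values, pm)
            cohort = ExpressionCohort(
                cohort.cohort_id, merged, cohort.subtype_of, scale=cohort.scale
            )
        cohorts.append(cohort)
    return cohorts


def _load_centered(config: RunConfig) -> list[ExpressionCohort]:
    out = Path(config.out_dir)
    cohorts = []
    for entry in config.cohorts:
        path = out / f"centered_{entry.cohort_id}.tsv"
        if not path.exists():
            raise PipelineError(
                f"{path} not found: run the preprocess stage first"
            )
        cohorts.append(
            ExpressionCohort(
                entry.cohort_id,
                read_matrix(path),
                read_labels(entry.labels),
                scale=entry.scale,
            )
        )
    return cohorts


def _load_common_genes(config: RunConfig) -> list[str]:
    path = Path(config.out_dir) / "common_genes.txt"
    if not path.exists():
        raise PipelineError(f"{path} not found: run the preprocess stage first")
    return path.read_text().split()


def _load_profiles(config: RunConfig) -> dict[str, ssgsea.PathwayProfile]:
    out = Path(config.out_dir)
    profiles = {}
    for entry in config.cohorts:
        path = out / f"pathway_profile_{entry.cohort_id}.tsv"
        if not path.exists():
            raise PipelineError(
                f"{path} not found: run the ssgsea stage first"
            )
        profiles[entry.cohort_id] = ssgsea.PathwayProfile(
            read_matrix(path), config.ssgsea_alpha
        )
    return profiles


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_preprocess(config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = _load_raw_cohorts(config)
    centered = [preprocess.median_center_genes(c) for c in cohorts]
    index = preprocess.intersect_genes(centered, config.min_common_genes)
    for c in centered:
        write_matrix(c.values, out / f"centered_{c.cohort_id}.tsv")
    (out / "common_genes.txt").write_text("\n".join(index.genes) + "\n")
    write_table(
        pd.DataFrame(index.excluded, columns=["cohort_id", "reason"]),
        out / "excluded_cohorts.tsv",
    )
    logger.info(
        "preprocess: %d cohorts, %d common genes, %d excluded",
        len(index.cohorts_included), len(index.genes), len(index.excluded),
    )


def stage_ssgsea(config: RunConfig) -> None:
    out = Path(config.out_dir)
    collection = read_gmt(config.gmt)
    cohorts = (
        _load_centered(config)
        if config.ssgsea_input == "centered"
        else _load_raw_cohorts(config)
    )
    for c in cohorts:
        profile = ssgsea.pathway_profile(
            c, collection, alpha=config.ssgsea_alpha,
            min_set_size=config.ssgsea_min_set_size,
        )
        write_matrix(profile.scores, out / f"pathway_profile_{c.cohort_id}.tsv")


def stage_correlate(config: RunConfig) -> None:
    out = Path(config.out_dir)
    cohorts = _load_centered(config)
    common = _load_common_genes(config)
    profiles = _load_profiles(config)
    ordered = sorted(cohorts, key=lambda c: c.cohort_id)
    for kind, kwargs in (
        ("transcriptional", {"common_genes": common}),
        ("pathway", {"profiles": profiles}),
    ):
        for i, ca in enumerate(ordered):
            for cb in ordered[i:]:
                cmap = correlation.cross_cohort_correlation(
                    ca, cb, profile_kind=kind, **kwargs
                )
                write_matrix(
                    cmap.rho,
                    out / f"rho_{kind}_{ca.cohort_id}_{cb.cohort_id}.tsv",
                )
        sim = correlation.subtype_similarity(cohorts, kind, **kwargs)
        write_matrix(sim.to_frame(), out / f"subtype_similarity_{kind}.tsv")


def stage_phylogeny(config: RunConfig) -> None:
    out = Path(config.out_dir)
    path = out / "subtype_similarity_transcriptional.tsv"
    if not path.exists():
        raise PipelineError(f"{path} not found: run the correlate stage first")
    sim = read_matrix(path)
    D = phylogeny.to_dissimilarity(sim.to_numpy())
    tree = phylogeny.average_linkage(D, list(sim.index))
    write_newick_file(tree, out / "subtype_phylogeny.nwk")
    write_table(
        pd.DataFrame(phylogeny.merge_table(tree)), out / "subtype_merges.tsv"
    )


def stage_gsea(config: RunConfig) -> None:
    out = Path(config.out_dir)
    collection = read_gmt(config.gmt)
    cohorts = _load_raw_cohorts(config)  # original scale: s2n floors need it
    table = gsea.gsea_all(
        cohorts, collection, n_perm=config.gsea_n_perm,
        seed=config.seed, weight_p=config.gsea_weight_p,
    )
    write_table(table, out / "gsea_table.tsv")
    retained = gsea.retain_significant(table, config.gsea_q_threshold)
    write_table(retained, out / "gsea_retained.tsv")
    tissue_of = {e.cohort_id: e.tissue for e in config.cohorts}
    write_table(
        gsea.tabulate_recurrence(retained, tissue_of),
        out / "pathway_recurrence.tsv",
    )


def stage_cluster_pathways(config: RunConfig) -> None:
    out = Path(config.out_dir)
    profiles = _load_profiles(config)
    cohorts = {e.cohort_id: read_labels(e.labels) for e in config.cohorts}
    common_sets = sorted(
        set.intersection(*(set(p.set_names) for p in profiles.values()))
    )
    if len(common_sets) < 3:
        raise PipelineError("fewer than 3 gene sets shared by all cohorts")
    pooled = pd.concat(
        [profiles[cid].scores.loc[common_sets] for cid in sorted(profiles)],
        axis=1,
    )
    tree = pathway_clustering.cluster_columns(pooled)
    group_of = pathway_clustering.split_two(tree)
    labels = {
        sample: f"{cid}.{sub}"
        for cid, label_map in cohorts.items()
        for sample, sub in label_map.items()
        if sample in group_of
    }
    split = pathway_clustering.subtype_enrichment(group_of, labels)
    write_table(
        pd.DataFrame(
            sorted(group_of.items()), columns=["sample", "group"]
        ),
        out / "pathway_groups.tsv",
    )
    write_table(split.stats, out / "subtype_group_enrichment.tsv")
    write_newick_file(tree, out / "pathway_dendrogram.nwk")


STAGE_FUNCS = {
    "preprocess": stage_preprocess,
    "ssgsea": stage_ssgsea,
    "correlate": stage_correlate,
    "phylogeny": stage_phylogeny,
    "gsea": stage_gsea,
    "cluster_pathways": stage_cluster_pathways,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order and write the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    executed = []
    for stage in STAGES:
        logger.info("stage %s ...", stage)
        try:
            STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        executed.append(stage)
    manifest: dict[str, Any] = {
        "stages": executed,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
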