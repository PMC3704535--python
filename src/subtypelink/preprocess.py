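"""Probe merging, per-cohort median centering, and gene-universe intersection.

Every cohort is normalized upstream; here probes mapping to the same gene
are merged by averaging, every gene row is centered on its within-cohort
median (both scale dialects), and cohorts are reduced to the gene universe
they share. A cohort whose overlap with the others is too small to support
profile correlation is excluded rather than silently correlated on a
handful of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import MappingError, PipelineError
from .io_formats import ExpressionCohort

logger = logging.getLogger(__name__)

#: default minimum pairwise common-gene count before a cohort is excluded;
#: sized for genome-wide microarray overlaps and configurable per run.
DEFAULT_MIN_COMMON = 5000


@dataclass
class CommonGeneIndex:
    """Result of intersecting cohort gene universes."""

    cohorts_included: list[str]
    genes: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)


def merge_probes_by_gene(
    probe_matrix: pd.DataFrame, probe_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples by averaging.

    Every probe row must be mapped; the merged value of a gene in a sample
    is the arithmetic mean of its probes' values in that sample. Gene rows
    are returned in sorted order for determinism.
    """
    unmapped = [p for p in probe_matrix.index if p not in probe_map]
    if unmapped:
        raise MappingError(f"probes without a gene mapping: {unmapped[:5]}")
    genes = [probe_map[p] for p in probe_matrix.index]
    merged = probe_matrix.groupby(pd.Index(genes, name="gene")).mean()
    return merged.sort_index()


def median_center_genes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Center every gene row on its median across this cohort's samples.

    Applied independently per cohort and to both scale dialects; idempotent.
    """
    centered = cohort.values.sub(cohort.values.median(axis=1), axis=0)
    return ExpressionCohort(
        cohort.cohort_id, centered, dict(cohort.subtype_of), scale=cohort.scale
    )


def intersect_genes(
    cohorts: Sequence[ExpressionCohort], min_common: int = DEFAULT_MIN_COMMON
) -> CommonGeneIndex:
    """Greedy gene-universe intersection across cohorts.

    Cohorts are visited in input order. Starting from the first cohort's
    universe, each subsequent cohort is intersected into the running set
    unless its overlap with that set falls below ``min_common``, in which
    case it is excluded and recorded with reason
    ``"insufficient_common_genes"``. Fewer than two surviving cohorts is a
    pipeline error. The resulting gene list is sorted.
    """
    if len(cohorts) < 2:
        raise PipelineError("gene intersection needs at least two cohorts")
    ids = [c.cohort_id for c in cohorts]
    if len(set(ids)) != len(ids):
        raise PipelineError(f"duplicate cohort ids: {ids}")
    current = set(cohorts[0].gene_ids)
    included = [cohorts[0].cohort_id]
    excluded: list[tuple[str, str]] = []
    for cohort in cohorts[1:]:
        overlap = current & set(cohort.gene_ids)
        if len(overlap) < min_common:
            logger.warning(
                "cohort %s excluded from the common gene universe: only %d "
                "genes shared with the running set (min_common=%d)",
                cohort.cohort_id, len(overlap), min_common,
            )
            excluded.append((cohort.cohort_id, "insufficient_common_genes"))
            continue
        current = overlap
        included.append(cohort.cohort_id)
    if len(included) < 2:
        raise PipelineError(
            "fewer than two cohorts share enough genes "
            f"(min_common={min_common})"
        )
    return CommonGeneIndex(included, sorted(current), excluded)
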