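"""Between-sample Spearman correlation of molecular profiles across cohorts.

A sample's transcriptional profile is its vector of median-centered gene
expression values over a common gene universe; its pathway profile is its
vector of ssGSEA enrichment scores. Spearman rank correlation (average
ranks on ties) between two samples' profiles is the between-sample
similarity; the similarity of two subtypes is the median of the pairwise
sample correlations, with self-pairs excluded on the diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, UndefinedCorrelationError
from .io_formats import ExpressionCohort
from .ssgsea import PathwayProfile

logger = logging.getLogger(__name__)

PROFILE_KINDS = ("transcriptional", "pathway")


@dataclass
class CorrelationMap:
    """Sample x sample Spearman rho between two cohorts' profiles."""

    cohort_a: str
    cohort_b: str
    rho: pd.DataFrame  # samples of A x samples of B
    profile_kind: str
    subtype_row_order: list[str]
    subtype_col_order: list[str]


@dataclass
class SubtypeSimilarity:
    """Subtype x subtype matrix of median pairwise Spearman correlations."""

    subtypes: list[tuple[str, str]]  # (cohort_id, subtype)
    median_rho: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c}.{s}" for c, s in self.subtypes]
        return pd.DataFrame(self.median_rho, index=labels, columns=labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.subtypes), k=1)
        return self.median_rho[iu]


# ---------------------------------------------------------------------------
# rank correlation primitives
# ---------------------------------------------------------------------------

def _column_ranks(X: np.ndarray) -> np.ndarray:
    """Average ranks of every column of a features x samples matrix."""
    return stats.rankdata(X, axis=0, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average-rank vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("rank correlation needs at least 3 observations")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "constant vector: rank correlation is undefined"
        )
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    return min(1.0, max(-1.0, rho))


def _pairwise_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman rho between every column of A and every column of B."""
    ra = _column_ranks(A)
    rb = _column_ranks(B)
    za = ra - ra.mean(axis=0)
    zb = rb - rb.mean(axis=0)
    sa = za.std(axis=0)
    sb = zb.std(axis=0)
    if (sa == 0).any() or (sb == 0).any():
        raise UndefinedCorrelationError(
            "constant profile column: rank correlation is undefined"
        )
    rho = (za / sa).T @ (zb / sb) / A.shape[0]
    return np.clip(rho, -1.0, 1.0)


# ---------------------------------------------------------------------------
# cohort-level maps
# ---------------------------------------------------------------------------

def _ordered_samples(subtype_of: Mapping[str, str], samples: Sequence[str]) -> list[str]:
    return sorted(samples, key=lambda s: (subtype_of[s], s))


def cross_cohort_correlation(
    cohort_a: ExpressionCohort,
    cohort_b: ExpressionCohort,
    common_genes: Sequence[str] | None = None,
    profile_kind: str = "transcriptional",
    profiles: Mapping[str, PathwayProfile] | None = None,
) -> CorrelationMap:
    """Spearman rho for every sample pair of two (possibly equal) cohorts.

    For the transcriptional profile both cohorts are restricted to
    ``common_genes``; for the pathway profile the shared set names of the
    two cohorts' ssGSEA profiles are used. Samples are grouped by subtype
    in the output ordering.
    """
    if profile_kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {profile_kind!r}")
    if profile_kind == "transcriptional":
        if common_genes is None:
            common_genes = sorted(
                set(cohort_a.gene_ids) & set(cohort_b.gene_ids)
            )
        features = list(common_genes)
        mat_a = cohort_a.values.loc[features]
        mat_b = cohort_b.values.loc[features]
    else:
        if profiles is None:
            raise PipelineError("pathway correlation needs ssGSEA profiles")
        pa = profiles[cohort_a.cohort_id].scores
        pb = profiles[cohort_b.cohort_id].scores
        features = sorted(set(pa.index) & set(pb.index))
        mat_a = pa.loc[features]
        mat_b = pb.loc[features]
    if len(features) < 3:
        raise PipelineError(
            f"only {len(features)} common features between "
            f"{cohort_a.cohort_id!r} and {cohort_b.cohort_id!r}"
        )
    samples_a = _ordered_samples(cohort_a.subtype_of, list(mat_a.columns))
    samples_b = _ordered_samples(cohort_b.subtype_of, list(mat_b.columns))
    rho = _pairwise_spearman(
        mat_a[samples_a].to_numpy(dtype=float),
        mat_b[samples_b].to_numpy(dtype=float),
    )
    return CorrelationMap(
        cohort_a.cohort_id,
        cohort_b.cohort_id,
        pd.DataFrame(rho, index=samples_a, columns=samples_b),
        profile_kind,
        [cohort_a.subtype_of[s] for s in samples_a],
        [cohort_b.subtype_of[s] for s in samples_b],
    )


def subtype_median_correlation(
    maps: Mapping[tuple[str, str], CorrelationMap],
    labels: Mapping[str, Mapping[str, str]],
) -> SubtypeSimilarity:
    """Summarize sample-level correlation maps into a subtype x subtype matrix.

    Entry ((cA, s), (cB, t)) is the median rho over all sample pairs with
    one sample in subtype s of cohort A and one in subtype t of cohort B.
    Within one cohort the diagonal (s == t) uses all unordered distinct
    pairs; self-correlations are excluded. Subtypes with fewer than two
    samples are excluded with a warning.
    """
    units: list[tuple[str, str]] = []
    for cid in sorted(labels):
        counts: dict[str, int] = {}
        for s, t in labels[cid].items():
            counts[t] = counts.get(t, 0) + 1
        for t in sorted(counts):
            if counts[t] < 2:
                logger.warning(
                    "subtype %s of cohort %s excluded from the similarity "
                    "matrix (fewer than 2 samples)", t, cid,
                )
                continue
            units.append((cid, t))
    k = len(units)
    med = np.full((k, k), np.nan)
    npairs = np.zeros((k, k), dtype=int)

    def _map_for(ca: str, cb: str) -> tuple[CorrelationMap, bool]:
        if (ca, cb) in maps:
            return maps[(ca, cb)], False
        if (cb, ca) in maps:
            return maps[(cb, ca)], True
        raise PipelineError(f"no correlation map for cohorts {ca!r}/{cb!r}")

    for i, (ca, s) in enumerate(units):
        for j in range(i, k):
            cb, t = units[j]
            cmap, transposed = _map_for(ca, cb)
            rho = cmap.rho.T if transposed else cmap.rho
            rows = [x for x in rho.index if labels[ca][x] == s]
            cols = [x for x in rho.columns if labels[cb][x] == t]
            block = rho.loc[rows, cols].to_numpy()
            if ca == cb and s == t:
                iu = np.triu_indices(len(rows), k=1)
                vals = block[iu]
            elif ca == cb:
                vals = block.ravel()
            else:
                vals = block.ravel()
            med[i, j] = med[j, i] = float(np.median(vals))
            npairs[i, j] = npairs[j, i] = vals.size
    return SubtypeSimilarity(units, med, npairs)


def subtype_similarity(
    cohorts: Sequence[ExpressionCohort],
    profile_kind: str = "transcriptional",
    common_genes: Sequence[str] | None = None,
    profiles: Mapping[str, PathwayProfile] | None = None,
) -> SubtypeSimilarity:
    """All-pairs driver: correlation maps for every cohort pair, then medians."""
    maps: dict[tuple[str, str], CorrelationMap] = {}
    ordered = sorted(cohorts, key=lambda c: c.cohort_id)
    for i, ca in enumerate(ordered):
        for cb in ordered[i:]:
            maps[(ca.cohort_id, cb.cohort_id)] = cross_cohort_correlation(
                ca, cb, common_genes=common_genes,
                profile_kind=profile_kind, profiles=profiles,
            )
    labels = {c.cohort_id: c.subtype_of for c in cohorts}
    return subtype_median_correlation(maps, labels)
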