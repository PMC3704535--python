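"""Single-sample GSEA enrichment scores forming the pathway profile.

For one sample, genes are ranked by decreasing expression (ties broken by
gene-id order). Walking down the ranked list, two empirical cumulative
distributions are compared at every position: ``P_in``, the cumulative
normalized weight of in-set genes (weight ``|expr|**alpha`` for ``alpha>0``,
1 for ``alpha=0``), and ``P_out``, the cumulative fraction of out-of-set
genes. The score of a gene set is the sum over all positions of
``P_in - P_out``: positive when the set's genes are coordinately
upregulated within that sample, negative when coordinately downregulated.

The per-sample score is computed in closed form from the in-set positions
rather than by materializing the full walk: summing a cumulative sum over
all ``G`` positions equals weighting each increment by the number of
positions at or after it, so

``score = sum_in w_i * (G - pos_i) / W  -  sum_out (G - pos_j) / (G - k)``

with 0-based positions, ``W`` the total in-set weight and ``k`` the in-set
size. The brute-force walk is kept in the test suite as an independent
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSetError, PipelineError
from .io_formats import ExpressionCohort, GeneSetCollection

logger = logging.getLogger(__name__)

#: GenePattern-style default weighting exponent.
DEFAULT_ALPHA = 0.25
#: sets with fewer surviving genes than this are dropped from the profile.
DEFAULT_MIN_SET_SIZE = 5


@dataclass
class PathwayProfile:
    """Gene sets x samples matrix of ssGSEA enrichment scores."""

    scores: pd.DataFrame  # sets x samples
    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise PipelineError("pathway profile contains non-finite scores")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _positions_desc(values: np.ndarray) -> np.ndarray:
    """0-based rank position of every entry when sorted by decreasing value.

    ``values`` columns must already be aligned to lexicographically sorted
    identifiers so that the stable sort breaks ties by id order.
    """
    order = np.argsort(-values, axis=0, kind="stable")
    return np.argsort(order, axis=0, kind="stable")


def _score_from_positions(
    pos: np.ndarray, w: np.ndarray, n_genes: int, set_size: int
) -> np.ndarray:
    """Closed-form ssGSEA score given in-set positions and weights."""
    tail = n_genes - pos  # number of positions at or after each in-set gene
    W = w.sum(axis=0)
    W = np.where(W == 0.0, 1.0, W)  # all-zero weights: fall back to uniform
    w_eff = np.where(w.sum(axis=0, keepdims=True) == 0.0, 1.0 / w.shape[0], w / W)
    p_in = (w_eff * tail).sum(axis=0)
    total_tail = n_genes * (n_genes + 1) / 2.0
    p_out = (total_tail - tail.sum(axis=0)) / (n_genes - set_size)
    return p_in - p_out


def ssgsea_score(
    expr: pd.Series, gene_set: frozenset[str] | set[str], alpha: float = DEFAULT_ALPHA
) -> float:
    """ssGSEA enrichment score of one gene set in one expression vector."""
    ids = np.asarray(expr.index, dtype=str)
    order_ids = np.argsort(ids, kind="stable")
    ids = ids[order_ids]
    x = expr.to_numpy(dtype=float)[order_ids]
    in_mask = np.isin(ids, sorted(gene_set))
    k = int(in_mask.sum())
    n = len(ids)
    if k == 0:
        raise DegenerateSetError("gene set has no overlap with the expression vector")
    if k == n:
        raise DegenerateSetError("gene set covers the entire gene universe")
    pos = _positions_desc(x[:, None])[:, 0]
    in_pos = pos[in_mask].astype(float)[:, None]
    if alpha > 0:
        w = np.abs(x[in_mask])[:, None] ** alpha
    else:
        w = np.ones((k, 1))
    return float(_score_from_positions(in_pos, w, n, k)[0])


def pathway_profile(
    cohort: ExpressionCohort,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> PathwayProfile:
    """Score every retained gene set in every sample of one cohort.

    Sets with fewer than ``min_set_size`` genes surviving the intersection
    with the cohort's universe are dropped (logged); a set covering every
    gene is degenerate; if nothing survives the profile cannot be built.
    """
    ids = np.asarray(cohort.values.index, dtype=str)
    order_ids = np.argsort(ids, kind="stable")
    ids = ids[order_ids]
    X = cohort.values.to_numpy(dtype=float)[order_ids]
    n_genes, n_samples = X.shape
    id_index = {g: i for i, g in enumerate(ids)}

    pos = _positions_desc(X).astype(float)  # genes x samples
    absw = np.abs(X) ** alpha if alpha > 0 else None

    kept: list[str] = []
    rows: list[np.ndarray] = []
    for name in collection.names:
        idx = np.fromiter(
            (id_index[g] for g in sorted(collection.sets[name]) if g in id_index),
            dtype=int,
        )
        k = idx.size
        if k == n_genes:
            raise DegenerateSetError(
                f"set {name!r} covers the entire gene universe of cohort "
                f"{cohort.cohort_id!r}"
            )
        if k < min_set_size:
            logger.info(
                "cohort %s: set %s dropped (%d genes after intersection "
                "< min_set_size=%d)", cohort.cohort_id, name, k, min_set_size,
            )
            continue
        w = absw[idx] if absw is not None else np.ones((k, n_samples))
        rows.append(_score_from_positions(pos[idx], w, n_genes, k))
        kept.append(name)
    if not kept:
        raise PipelineError(
            f"cohort {cohort.cohort_id!r}: every gene set was dropped; "
            "cannot build a pathway profile"
        )
    scores = pd.DataFrame(np.vstack(rows), index=kept, columns=cohort.sample_ids)
    return PathwayProfile(scores, alpha)
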