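"""Clustering of the pooled pathway profile and subtype overrepresentation.

ssGSEA scores from all cohorts are pooled into one gene-sets x samples
matrix (raw scores, no rescaling), samples are clustered by average
linkage on ``1 - spearman_rho`` between their score vectors, the
dendrogram is cut at the root into two groups K1/K2, and each subtype is
tested for overrepresentation in one of the groups with a Pearson
chi-squared test on the 2x2 table (subtype membership x group membership,
no continuity correction; Fisher's exact test when any expected cell is
below 5, flagged in the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError
from .correlation import _pairwise_spearman
from .phylogeny import SubtypeTree, average_linkage

logger = logging.getLogger(__name__)


@dataclass
class GroupSplit:
    """Two-group partition of samples plus per-subtype enrichment tests."""

    group_of: dict[str, str]  # sample -> "K1" | "K2"
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # stats columns: subtype, n, n_k1, n_k2, chi2, p_value, enriched_group, test


def cluster_columns(scores: pd.DataFrame) -> SubtypeTree:
    """Column (sample) dendrogram of a pooled sets x samples score matrix.

    Dissimilarity is ``1 - spearman`` between sample score vectors; columns
    with zero rank variance (constant scores) are dropped with a warning.
    """
    if scores.shape[0] < 3:
        raise PipelineError("need at least 3 gene sets to correlate samples")
    X = scores.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0, method="average")
    keep = ranks.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(scores.columns, keep) if not k]
        logger.warning(
            "dropping %d constant pathway-profile columns: %s",
            len(dropped), dropped[:5],
        )
    cols = [c for c, k in zip(scores.columns, keep) if k]
    if len(cols) < 2:
        raise PipelineError("fewer than 2 usable samples after dropping "
                            "constant columns")
    rho = _pairwise_spearman(X[:, keep], X[:, keep])
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry for the agglomerator
    return average_linkage(D, [str(c) for c in cols])


def split_two(tree: SubtypeTree) -> dict[str, str]:
    """Cut the dendrogram at the root into K1/K2.

    The two children of the final merge define the groups; K1 is the group
    containing the lexicographically smallest sample id.
    """
    if not tree.merges:
        raise PipelineError("cannot split a single-leaf tree")
    sets = tree.leaf_sets()
    left, right, _h = tree.merges[-1]
    a, b = sorted(sets[left]), sorted(sets[right])
    if min(a) <= min(b):
        k1, k2 = a, b
    else:
        k1, k2 = b, a
    out = {s: "K1" for s in k1}
    out.update({s: "K2" for s in k2})
    return out


def subtype_enrichment(
    group_of: Mapping[str, str], labels: Mapping[str, str]
) -> GroupSplit:
    """Chi-squared overrepresentation of every subtype in K1 vs K2.

    ``labels`` maps each sample to its (cohort-qualified) subtype. For
    each subtype the 2x2 table is [subtype, others] x [K1, K2]; the
    enriched group is the one where the subtype's observed count exceeds
    its expectation under independence.
    """
    missing = sorted(set(group_of) - set(labels))
    if missing:
        raise PipelineError(f"samples without a subtype label: {missing[:5]}")
    samples = sorted(group_of)
    groups = np.asarray([group_of[s] for s in samples])
    subs = np.asarray([labels[s] for s in samples])
    n_k1 = int((groups == "K1").sum())
    n_k2 = int((groups == "K2").sum())
    rows = []
    for subtype in sorted(set(subs)):
        is_sub = subs == subtype
        a = int((is_sub & (groups == "K1")).sum())
        b = int((is_sub & (groups == "K2")).sum())
        table = np.array([[a, b], [n_k1 - a, n_k2 - b]])
        n_sub = a + b
        row = {
            "subtype": subtype, "n": n_sub, "n_k1": a, "n_k2": b,
            "chi2": np.nan, "p_value": np.nan,
            "enriched_group": "none", "test": "chi2",
        }
        if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
            logger.warning(
                "subtype %s: degenerate 2x2 table (zero margin), test skipped",
                subtype,
            )
            row["test"] = "skipped"
            rows.append(row)
            continue
        expected = stats.contingency.expected_freq(table)
        if expected.min() < 5:
            _odds, p = stats.fisher_exact(table)
            row["test"] = "fisher"
            row["p_value"] = float(p)
        else:
            chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
            row["chi2"] = float(chi2)
            row["p_value"] = float(p)
        if a > expected[0, 0]:
            row["enriched_group"] = "K1"
        elif b > expected[0, 1]:
            row["enriched_group"] = "K2"
        rows.append(row)
    stats_df = pd.DataFrame(
        rows,
        columns=["subtype", "n", "n_k1", "n_k2", "chi2", "p_value",
                 "enriched_group", "test"],
    )
    return GroupSplit(dict(group_of), stats_df)
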