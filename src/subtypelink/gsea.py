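"""One-vs-rest GSEA per subtype with a phenotype-permutation null.

Within each cohort, every subtype is contrasted against all remaining
samples of the same cohort. Genes are ranked by signal-to-noise ratio on
absolute-intensity cohorts — ``(mu_in - mu_rest) / (sd_in + sd_rest)`` with
the standard variance-stabilization floor ``sd <- max(sd, 0.2 * |mu|)``
(and ``sd <- 0.2`` when both sd and mu vanish) — or by the difference of
class means on log-ratio cohorts. The enrichment score (ES) of a gene set
is the signed maximal deviation of the weighted Kolmogorov-Smirnov running
sum: hits increment by ``|metric| ** p`` normalized by total in-set
weight, misses decrement by ``1 / (N - |S|)``.

The null distribution comes from permuting the one-vs-rest phenotype
labels within the cohort. The normalized enrichment score (NES) divides
the ES by the mean magnitude of same-sign null ES values of the same set;
the nominal p-value is the fraction of same-sign null ES at least as
extreme; the FDR q-value is the GSEA-style ratio of tail fractions on
sign-separated NES pools across all sets, with a running-minimum
monotonicity enforcement and capped at 1.

When the running sum's largest positive and negative deviations tie in
magnitude the positive one is reported; every route (single walk, batch
permutation kernel, the brute-force oracle in the tests) applies the same
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateSetError, PipelineError
from .io_formats import ExpressionCohort, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_WEIGHT_P = 1.0
DEFAULT_Q_THRESHOLD = 0.25
DEFAULT_MIN_SET_SIZE = 5
MIN_CLASS_SIZE = 3  # hard floor for the one-vs-rest contrast
SMALL_CLASS_WARN = 7
#: when the largest positive and negative deviations of the running sum tie
#: to within this absolute tolerance, the positive one is reported; the
#: tolerance keeps the single-walk and batch routes in exact agreement.
ES_SIGN_TOL = 1e-9
#: a gene set dysregulated in subtypes of >= this many tissues is "common".
COMMON_MIN_TISSUES = 5

TABLE_COLUMNS = [
    "cohort_id", "subtype", "set_name", "es", "nes",
    "p_nominal", "fdr_q", "direction",
]


@dataclass
class RankedList:
    """Genes ordered by decreasing metric, ties broken by gene-id order."""

    gene_ids: np.ndarray
    metric: np.ndarray


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def _class_masks(labels: Sequence[str] | np.ndarray, subtype: str) -> np.ndarray:
    labels = np.asarray(labels)
    return labels == subtype


def signal_to_noise(values: pd.DataFrame, in_mask: Sequence[bool]) -> pd.Series:
    """Per-gene signal-to-noise ratio between the in-class and the rest."""
    in_mask = np.asarray(in_mask, dtype=bool)
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise PipelineError("signal-to-noise needs >= 2 samples per class")
    X = values.to_numpy(dtype=float)
    Z = in_mask.astype(float)[:, None]
    metric = _batch_s2n(X, Z, int(in_mask.sum()))[:, 0]
    return pd.Series(metric, index=values.index)


def class_mean_difference(values: pd.DataFrame, in_mask: Sequence[bool]) -> pd.Series:
    """Per-gene difference of class means (log-ratio scale)."""
    in_mask = np.asarray(in_mask, dtype=bool)
    if in_mask.sum() < 1 or (~in_mask).sum() < 1:
        raise PipelineError("both classes must be non-empty")
    X = values.to_numpy(dtype=float)
    mu_in = X[:, in_mask].mean(axis=1)
    mu_rest = X[:, ~in_mask].mean(axis=1)
    return pd.Series(mu_in - mu_rest, index=values.index)


def _floored_sd(sd: np.ndarray, mu: np.ndarray) -> np.ndarray:
    out = np.maximum(sd, 0.2 * np.abs(mu))
    return np.where((sd == 0.0) & (mu == 0.0), 0.2, out)


def _batch_s2n(X: np.ndarray, Z: np.ndarray, k: int) -> np.ndarray:
    """Signal-to-noise for many phenotype assignments at once.

    ``X`` is genes x samples; ``Z`` is samples x P with exactly ``k`` ones
    per column marking the in-class samples.
    """
    n = X.shape[1]
    s_in = X @ Z
    ss_in = (X * X) @ Z
    s_all = X.sum(axis=1, keepdims=True)
    ss_all = (X * X).sum(axis=1, keepdims=True)
    mu_in = s_in / k
    mu_out = (s_all - s_in) / (n - k)
    var_in = np.maximum((ss_in - k * mu_in**2) / (k - 1), 0.0)
    var_out = np.maximum(
        ((ss_all - ss_in) - (n - k) * mu_out**2) / (n - k - 1), 0.0
    )
    sd_in = _floored_sd(np.sqrt(var_in), mu_in)
    sd_out = _floored_sd(np.sqrt(var_out), mu_out)
    return (mu_in - mu_out) / (sd_in + sd_out)


def _batch_mean_diff(X: np.ndarray, Z: np.ndarray, k: int) -> np.ndarray:
    n = X.shape[1]
    s_in = X @ Z
    s_all = X.sum(axis=1, keepdims=True)
    return s_in / k - (s_all - s_in) / (n - k)


def metric_for_scale(scale: str) -> str:
    """Which ranking metric a cohort's scale dialect implies."""
    return "s2n" if scale == "absolute" else "mean_diff"


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def rank_genes(metric: pd.Series) -> RankedList:
    """Order genes by decreasing metric, ties by lexicographic gene id."""
    ids = np.asarray(metric.index, dtype=str)
    vals = metric.to_numpy(dtype=float)
    order = np.lexsort((ids, -vals))
    return RankedList(ids[order], vals[order])


def enrichment_score(
    ranked: RankedList,
    gene_set: frozenset[str] | set[str],
    weight_p: float = DEFAULT_WEIGHT_P,
) -> tuple[float, np.ndarray]:
    """Classic weighted KS walk; returns (es, running sum over positions)."""
    hit = np.isin(ranked.gene_ids, sorted(gene_set))
    n = hit.size
    k = int(hit.sum())
    if k == 0:
        raise DegenerateSetError("gene set has no overlap with the ranked list")
    if k == n:
        raise DegenerateSetError("gene set covers the entire ranked list")
    if weight_p > 0:
        w = np.where(hit, np.abs(ranked.metric) ** weight_p, 0.0)
    else:
        w = hit.astype(float)
    W = w.sum()
    if W == 0.0:
        w = hit.astype(float)
        W = float(k)
    running = np.cumsum(w / W - (~hit) / (n - k))
    pos = max(running.max(), 0.0)
    neg = min(running.min(), 0.0)
    es = pos if pos >= -neg - ES_SIGN_TOL else neg
    return float(es), running


def _batch_es(
    inv_pos: np.ndarray,
    metric: np.ndarray,
    set_idx: np.ndarray,
    weight_p: float,
) -> np.ndarray:
    """ES of one gene set under many rankings at once.

    ``inv_pos[g, j]`` is the 0-based rank position of gene ``g`` in
    ranking ``j``; ``metric`` is aligned genes x P. Evaluates the running
    sum only at in-set positions (its extrema sit at a hit or just before
    one), which is exact and avoids materializing the full walk.
    """
    G = inv_pos.shape[0]
    k = set_idx.size
    pos = inv_pos[set_idx, :].astype(float)
    if weight_p > 0:
        w = np.abs(metric[set_idx, :]) ** weight_p
    else:
        w = np.ones_like(pos)
    sorter = np.argsort(pos, axis=0)
    pos = np.take_along_axis(pos, sorter, axis=0)
    w = np.take_along_axis(w, sorter, axis=0)
    cw = np.cumsum(w, axis=0)
    W = cw[-1, :]
    degenerate = W == 0.0
    if degenerate.any():
        # all-zero weights: fall back to the unweighted statistic
        cw[:, degenerate] = np.arange(1, k + 1, dtype=float)[:, None]
        W = np.where(degenerate, float(k), W)
    miss = (pos - np.arange(k, dtype=float)[:, None]) / (G - k)
    after = cw / W - miss
    before = (cw - w) / W - miss
    if degenerate.any():
        before[:, degenerate] = (
            cw[:, degenerate] - 1.0
        ) / W[degenerate] - miss[:, degenerate]
    a = np.maximum(after.max(axis=0), 0.0)
    b = np.minimum(before.min(axis=0), 0.0)
    return np.where(a >= -b - ES_SIGN_TOL, a, b)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _gsea_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q on sign-separated NES pools.

    ``nes``: observed NES per set (NaN allowed: excluded, q = 1).
    ``null_nes``: sets x permutations normalized null ES.
    """
    q = np.ones_like(nes)
    null_flat = null_nes[np.isfinite(null_nes)]
    for sign in (1, -1):
        obs_idx = np.nonzero(np.isfinite(nes) & (np.sign(nes) == sign))[0]
        if obs_idx.size == 0:
            continue
        obs = nes[obs_idx]
        pool = null_flat[np.sign(null_flat) == sign]
        n_obs = obs.size
        for rank_i in np.argsort(-sign * obs):  # most extreme first
            i = obs_idx[rank_i]
            v = nes[i]
            if sign > 0:
                numer = float(np.mean(pool >= v)) if pool.size else 0.0
                denom = float(np.mean(obs >= v))
            else:
                numer = float(np.mean(pool <= v)) if pool.size else 0.0
                denom = float(np.mean(obs <= v))
            q[i] = min(numer / denom, 1.0)
        # monotonicity: a more extreme NES never gets a larger q, so each
        # set's q is the running minimum of the raw q over itself and every
        # less extreme same-sign set
        order = np.argsort(sign * obs)  # ascending extremity
        running = np.inf
        for rank_i in order:
            i = obs_idx[rank_i]
            running = min(running, q[i])
            q[i] = running
    return q


def _retained_set_indices(
    gene_index: Mapping[str, int],
    collection: GeneSetCollection,
    n_genes: int,
    min_set_size: int,
    context: str,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name in collection.names:
        idx = np.fromiter(
            (gene_index[g] for g in sorted(collection.sets[name]) if g in gene_index),
            dtype=int,
        )
        if idx.size == n_genes:
            raise DegenerateSetError(
                f"set {name!r} covers the entire gene universe ({context})"
            )
        if idx.size < min_set_size:
            logger.info("%s: set %s dropped (%d genes < %d)",
                        context, name, idx.size, min_set_size)
            continue
        out[name] = idx
    return out


def permutation_test(
    cohort: ExpressionCohort,
    subtype: str,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | Sequence[int] = 0,
    weight_p: float = DEFAULT_WEIGHT_P,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame | None:
    """One-vs-rest GSEA of one subtype with a phenotype-permutation null.

    Returns one row per retained gene set (es, nes, p_nominal, fdr_q,
    direction), or ``None`` when the subtype is smaller than the hard
    minimum class size (skipped with a warning).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be at least 100")
    labels = np.asarray([cohort.subtype_of[s] for s in cohort.sample_ids])
    in_mask = _class_masks(labels, subtype)
    k_in = int(in_mask.sum())
    n = labels.size
    if min(k_in, n - k_in) < MIN_CLASS_SIZE:
        logger.warning(
            "cohort %s: subtype %s skipped (class sizes %d vs %d below "
            "min_class_size=%d)", cohort.cohort_id, subtype, k_in,
            n - k_in, MIN_CLASS_SIZE,
        )
        return None
    if min(k_in, n - k_in) < SMALL_CLASS_WARN:
        logger.warning(
            "cohort %s: subtype %s has a small class (%d vs %d); "
            "permutation null will be coarse", cohort.cohort_id, subtype,
            k_in, n - k_in,
        )

    # genes sorted lexicographically so stable sorts break metric ties by id
    ids = np.asarray(cohort.values.index, dtype=str)
    gene_order = np.argsort(ids, kind="stable")
    ids = ids[gene_order]
    X = cohort.values.to_numpy(dtype=float)[gene_order]
    G = X.shape[0]
    gene_index = {g: i for i, g in enumerate(ids)}
    sets = _retained_set_indices(
        gene_index, collection, G, min_set_size,
        f"cohort {cohort.cohort_id} subtype {subtype}",
    )
    if not sets:
        raise PipelineError(
            f"cohort {cohort.cohort_id!r}: no gene set survives the "
            "minimum-size filter"
        )

    rng = np.random.default_rng(seed)
    Z = np.empty((n, n_perm + 1))
    Z[:, 0] = in_mask.astype(float)
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k_in]
    Zperm = np.zeros((n_perm, n))
    np.put_along_axis(Zperm, picks, 1.0, axis=1)
    Z[:, 1:] = Zperm.T

    kind = metric_for_scale(cohort.scale)
    if kind == "s2n":
        metric = _batch_s2n(X, Z, k_in)
    else:
        metric = _batch_mean_diff(X, Z, k_in)
    order = np.argsort(-metric, axis=0, kind="stable")
    inv_pos = np.argsort(order, axis=0, kind="stable")

    names = list(sets)
    es = np.empty((len(names), n_perm + 1))
    for i, name in enumerate(names):
        es[i] = _batch_es(inv_pos, metric, sets[name], weight_p)

    es_obs = es[:, 0]
    null = es[:, 1:]
    pos_null = np.where(null > 0, null, np.nan)
    neg_null = np.where(null < 0, null, np.nan)
    with np.errstate(invalid="ignore"):
        mean_pos = np.nanmean(pos_null, axis=1)
        mean_neg = np.nanmean(np.abs(neg_null), axis=1)
    n_pos = (null > 0).sum(axis=1)
    n_neg = (null < 0).sum(axis=1)

    nes = np.full_like(es_obs, np.nan)
    p = np.ones_like(es_obs)
    null_nes = np.full_like(null, np.nan)
    for i in range(len(names)):
        if es_obs[i] >= 0:
            if n_pos[i] > 0:
                nes[i] = es_obs[i] / mean_pos[i]
                p[i] = float((null[i] >= es_obs[i]).sum()) / n_pos[i]
        else:
            if n_neg[i] > 0:
                nes[i] = es_obs[i] / mean_neg[i]
                p[i] = float((null[i] <= es_obs[i]).sum()) / n_neg[i]
        if n_pos[i] > 0:
            sel = null[i] > 0
            null_nes[i, sel] = null[i, sel] / mean_pos[i]
        if n_neg[i] > 0:
            sel = null[i] < 0
            null_nes[i, sel] = null[i, sel] / mean_neg[i]
    p = np.clip(p, 0.0, 1.0)
    q = _gsea_fdr(nes, null_nes)

    return pd.DataFrame(
        {
            "cohort_id": cohort.cohort_id,
            "subtype": subtype,
            "set_name": names,
            "es": es_obs,
            "nes": nes,
            "p_nominal": p,
            "fdr_q": q,
            "direction": np.where(es_obs >= 0, "up", "down"),
        }
    )


def gsea_all(
    cohorts: Sequence[ExpressionCohort],
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight_p: float = DEFAULT_WEIGHT_P,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Run the one-vs-rest permutation GSEA for every subtype of every cohort.

    Child RNG seeds are derived deterministically from ``seed`` and the
    (sorted) cohort and subtype indices, so results do not depend on input
    order.
    """
    frames: list[pd.DataFrame] = []
    for ci, cohort in enumerate(sorted(cohorts, key=lambda c: c.cohort_id)):
        for si, subtype in enumerate(cohort.subtypes):
            rows = permutation_test(
                cohort, subtype, collection,
                n_perm=n_perm, seed=[seed, ci, si],
                weight_p=weight_p, min_set_size=min_set_size,
            )
            if rows is not None:
                frames.append(rows)
    if not frames:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# retention and cross-tissue recurrence
# ---------------------------------------------------------------------------

def retain_significant(
    table: pd.DataFrame, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> pd.DataFrame:
    """Keep the (cohort, subtype, set) rows with FDR q strictly below the
    threshold; a set is thereby retained iff it is significant in at least
    one subtype."""
    if table.empty:
        return table.copy()
    return table[table["fdr_q"] < q_threshold].reset_index(drop=True)


def tabulate_recurrence(
    filtered: pd.DataFrame,
    tissue_of_cohort: Mapping[str, str],
    common_min_tissues: int = COMMON_MIN_TISSUES,
) -> pd.DataFrame:
    """Cross-tissue recurrence of significantly dysregulated gene sets.

    One output row per gene set: its subtype hits (tissue:subtype:direction),
    the number of distinct subtypes and tissues, and a recurrence class —
    ``tissue_specific`` (exactly one tissue), ``common`` (at least
    ``common_min_tissues`` tissues) or ``intermediate``.
    """
    unmapped = sorted(
        set(filtered["cohort_id"]) - set(tissue_of_cohort)
    ) if not filtered.empty else []
    if unmapped:
        raise ConfigError(f"cohorts without a tissue mapping: {unmapped}")
    rows = []
    for set_name, grp in filtered.groupby("set_name", sort=True):
        hits = sorted(
            (tissue_of_cohort[r.cohort_id], f"{r.cohort_id}.{r.subtype}", r.direction)
            for r in grp.itertuples()
        )
        tissues = {h[0] for h in hits}
        n_tissues = len(tissues)
        if n_tissues == 1:
            klass = "tissue_specific"
        elif n_tissues >= common_min_tissues:
            klass = "common"
        else:
            klass = "intermediate"
        rows.append(
            {
                "set_name": set_name,
                "hits": ";".join(":".join(h) for h in hits),
                "n_subtypes": len(hits),
                "n_tissues": n_tissues,
                "class": klass,
            }
        )
    return pd.DataFrame(
        rows, columns=["set_name", "hits", "n_subtypes", "n_tissues", "class"]
    )
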