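import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import subtypelink as sl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cohort() -> sl.ExpressionCohort:
    """5 genes x 6 samples, two subtypes, handy for exact-value checks."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(5, 6)), index=genes, columns=samples
    )
    labels = {s: ("t1" if i < 3 else "t2") for i, s in enumerate(samples)}
    return sl.ExpressionCohort("tiny", values, labels)


@pytest.fixture
def tiny_collection() -> sl.GeneSetCollection:
    return sl.GeneSetCollection(
        {"SETA": frozenset({"g0", "g1"}), "SETB": frozenset({"g2", "g3", "g4"})},
        {"SETA": "na", "SETB": "na"},
    )


def brute_force_walk_es(order_metric, hit_mask, weight_p):
    """Independent ES oracle: explicit running sum over every position.

    ``order_metric``/``hit_mask`` are already in ranked order. Applies the
    positive-preferred tie rule shared by all routes.
    """
    n = len(hit_mask)
    k = sum(hit_mask)
    w = [abs(m) ** weight_p if h else 0.0 for m, h in zip(order_metric, hit_mask)]
    if weight_p == 0:
        w = [1.0 if h else 0.0 for h in hit_mask]
    W = sum(w)
    if W == 0:
        w = [1.0 if h else 0.0 for h in hit_mask]
        W = float(k)
    running = 0.0
    lo, hi = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / W
        else:
            running -= 1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo - 1e-9 else lo


def brute_force_ssgsea(expr_sorted_ids, expr_values, in_set, alpha):
    """Independent ssGSEA oracle: explicit cumulative-distribution sum.

    ``expr_sorted_ids``/``expr_values`` must be aligned; ranking (decreasing
    value, ties by id order) is done here from scratch.
    """
    order = sorted(
        range(len(expr_sorted_ids)),
        key=lambda i: (-expr_values[i], expr_sorted_ids[i]),
    )
    hits = [expr_sorted_ids[i] in in_set for i in order]
    vals = [expr_values[i] for i in order]
    n = len(order)
    k = sum(hits)
    w = [abs(v) ** alpha if alpha > 0 else 1.0 for v in vals]
    W = sum(wi for wi, h in zip(w, hits) if h)
    if W == 0:
        w = [1.0] * n
        W = float(k)
    score = 0.0
    cin = 0.0
    cout = 0.0
    for i in range(n):
        if hits[i]:
            cin += w[i] / W
        else:
            cout += 1.0 / (n - k)
        score += cin - cout
    return score
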