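"""Multi-cohort expression generator with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in
real multi-cohort subtyping data: several cohorts over partially
overlapping gene universes, 2-7 subtypes per cohort, Gaussian noise on the
log2 scale, and planted "shared program" gene modules — blocks of genes
coordinately shifted by an effect size ``delta`` (log2 units) in the
samples of designated (cohort, subtype) members. A program shared by
subtypes of two different cohorts makes them cross-tissue partners; the
same module doubles as that subtype's planted up- or down-dysregulated
gene set for enrichment testing. Both scale dialects are emitted:
``absolute`` cohorts sit near a gene-level baseline of ~8 log2 units,
``log_ratio`` cohorts near 0.

The default desk-scale preset (3 cohorts x 60 samples x 2,000 genes,
3 subtypes each, 4 programs of 50 genes, delta = 1.0, noise_sd = 1.0) is
sized so the full pipeline runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .io_formats import ExpressionCohort, GeneSetCollection

#: log2 baseline around which absolute-dialect intensities sit.
BASELINE_MU = 8.0
#: spread of gene-level baselines around BASELINE_MU.
BASELINE_SD = 1.0


@dataclass
class Program:
    """A planted gene module shared by designated (cohort, subtype) members."""

    name: str
    genes: tuple[str, ...]
    members: tuple[tuple[str, str], ...]  # (cohort_id, subtype)
    delta: float
    direction: str = "up"  # "up" | "down"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise DesignError(f"program {self.name!r}: delta must be >= 0")
        if self.direction not in ("up", "down"):
            raise DesignError(f"program {self.name!r}: bad direction")


@dataclass
class CohortSpec:
    cohort_id: str
    tissue: str
    n_genes: int
    n_samples: int
    subtype_proportions: dict[str, float]
    overlap: float = 0.9  # fraction of genes drawn from the global universe
    scale: str = "absolute"

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DesignError(
                f"cohort {self.cohort_id!r}: subtype proportions sum to "
                f"{total}, not 1"
            )
        if not 2 <= len(self.subtype_proportions) <= 7:
            raise DesignError(
                f"cohort {self.cohort_id!r}: need 2-7 subtypes"
            )
        if not 0.0 < self.overlap <= 1.0:
            raise DesignError(f"cohort {self.cohort_id!r}: bad overlap")


@dataclass
class SyntheticDesign:
    cohorts: list[CohortSpec]
    programs: list[Program]
    n_global_genes: int
    noise_sd: float = 1.0
    null_mode: bool = False
    seed: int = 0
    #: optional planted two-group assignment of (cohort, subtype) slots,
    #: recorded in the ground truth for split-recovery checks
    group_of: dict[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate cohort ids {ids}")
        universe = set(global_universe(self.n_global_genes))
        for p in self.programs:
            if not set(p.genes) <= universe:
                raise DesignError(
                    f"program {p.name!r}: module genes outside the global "
                    "universe"
                )
            for cid, sub in p.members:
                spec = next((c for c in self.cohorts if c.cohort_id == cid), None)
                if spec is None:
                    raise DesignError(
                        f"program {p.name!r}: unknown cohort {cid!r}"
                    )
                if sub not in spec.subtype_proportions:
                    raise DesignError(
                        f"program {p.name!r}: cohort {cid!r} has no subtype "
                        f"{sub!r}"
                    )


def global_universe(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def default_design(
    seed: int = 0,
    delta: float = 1.0,
    noise_sd: float = 1.0,
    null_mode: bool = False,
    n_genes: int = 2000,
    n_samples: int = 60,
    module_size: int = 50,
) -> SyntheticDesign:
    """Desk-scale preset: 3 cohorts, 3 subtypes each, 4 cross-tissue programs.

    Partnerships (shared programs, all different tissue pairs):
    PROG1 (up):   (cohA, s1) - (cohB, s1)
    PROG2 (up):   (cohB, s2) - (cohC, s2)
    PROG3 (up):   (cohA, s2) - (cohC, s1)
    PROG4 (down): (cohA, s3) - (cohB, s3)
    cohC is emitted in the two-color log-ratio dialect.
    """
    props = {"s1": 1 / 3, "s2": 1 / 3, "s3": 1 / 3}
    cohorts = [
        CohortSpec("cohA", "breast", n_genes, n_samples, dict(props)),
        CohortSpec("cohB", "glioma", n_genes, n_samples, dict(props)),
        CohortSpec("cohC", "liver", n_genes, n_samples, dict(props),
                   scale="log_ratio"),
    ]
    members = [
        (("cohA", "s1"), ("cohB", "s1"), "up"),
        (("cohB", "s2"), ("cohC", "s2"), "up"),
        (("cohA", "s2"), ("cohC", "s1"), "up"),
        (("cohA", "s3"), ("cohB", "s3"), "down"),
    ]
    universe = global_universe(n_genes)
    rng = np.random.default_rng([seed, 7])
    module_genes = rng.choice(
        n_genes, size=module_size * len(members), replace=False
    )
    programs = []
    for i, (m1, m2, direction) in enumerate(members):
        genes = tuple(
            universe[g]
            for g in sorted(module_genes[i * module_size:(i + 1) * module_size])
        )
        programs.append(
            Program(f"PROG{i + 1}", genes, (m1, m2), delta, direction)
        )
    return SyntheticDesign(
        cohorts, programs, n_genes,
        noise_sd=noise_sd, null_mode=null_mode, seed=seed,
    )


def two_group_design(
    seed: int = 0,
    delta: float = 1.0,
    noise_sd: float = 1.0,
    n_genes: int = 2000,
    n_samples: int = 60,
    module_size: int = 50,
) -> SyntheticDesign:
    """Preset with two planted program groups spanning all cohorts.

    Subtypes are assigned to planted groups G1/G2; module M1 is up in G1
    subtypes and down in G2 subtypes, module M2 the reverse, so pooled
    pathway profiles separate into two blocks at the dendrogram root.
    """
    props = {"s1": 1 / 3, "s2": 1 / 3, "s3": 1 / 3}
    cohorts = [
        CohortSpec("cohA", "breast", n_genes, n_samples, dict(props)),
        CohortSpec("cohB", "glioma", n_genes, n_samples, dict(props)),
        CohortSpec("cohC", "liver", n_genes, n_samples, dict(props),
                   scale="log_ratio"),
    ]
    g1 = (("cohA", "s1"), ("cohB", "s2"), ("cohC", "s3"), ("cohA", "s3"))
    g2 = (("cohA", "s2"), ("cohB", "s1"), ("cohB", "s3"),
          ("cohC", "s1"), ("cohC", "s2"))
    universe = global_universe(n_genes)
    rng = np.random.default_rng([seed, 11])
    picks = rng.choice(n_genes, size=2 * module_size, replace=False)
    m1 = tuple(universe[g] for g in sorted(picks[:module_size]))
    m2 = tuple(universe[g] for g in sorted(picks[module_size:]))
    programs = [
        Program("GROUP1_M1", m1, g1, delta, "up"),
        Program("GROUP2_M1", m1, g2, delta, "down"),
        Program("GROUP1_M2", m2, g1, delta, "down"),
        Program("GROUP2_M2", m2, g2, delta, "up"),
    ]
    group_of = {slot: "G1" for slot in g1}
    group_of.update({slot: "G2" for slot in g2})
    return SyntheticDesign(
        cohorts, programs, n_genes,
        noise_sd=noise_sd, seed=seed, group_of=group_of,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _subtype_counts(spec: CohortSpec) -> dict[str, int]:
    """Largest-remainder rounding of subtype proportions to sample counts."""
    raw = {t: spec.subtype_proportions[t] * spec.n_samples
           for t in sorted(spec.subtype_proportions)}
    counts = {t: int(np.floor(v)) for t, v in raw.items()}
    short = spec.n_samples - sum(counts.values())
    by_frac = sorted(raw, key=lambda t: (-(raw[t] - counts[t]), t))
    for t in by_frac[:short]:
        counts[t] += 1
    return counts


def generate_cohorts(
    design: SyntheticDesign,
) -> tuple[list[ExpressionCohort], dict]:
    """Generate every cohort plus the planted ground-truth record.

    The ground truth lists, per program, the module genes, direction and
    member slots; the cross-tissue partnerships (all member pairs from
    distinct cohorts); and the planted two-group assignment when the
    design defines one.
    """
    rng = np.random.default_rng([design.seed, 1])
    universe = global_universe(design.n_global_genes)
    mu_global = dict(
        zip(universe,
            rng.normal(BASELINE_MU, BASELINE_SD, size=design.n_global_genes))
    )

    required: dict[str, set[str]] = {c.cohort_id: set() for c in design.cohorts}
    for p in design.programs:
        for cid, _sub in p.members:
            required[cid].update(p.genes)

    cohorts: list[ExpressionCohort] = []
    for spec in design.cohorts:
        crng = np.random.default_rng([design.seed, 2, hash_id(spec.cohort_id)])
        n_shared = int(round(spec.overlap * spec.n_genes))
        need = sorted(required[spec.cohort_id])
        if len(need) > n_shared:
            raise DesignError(
                f"cohort {spec.cohort_id!r}: module genes ({len(need)}) do "
                f"not fit in its shared-universe quota ({n_shared})"
            )
        rest_pool = sorted(set(universe) - set(need))
        extra = crng.choice(
            len(rest_pool), size=n_shared - len(need), replace=False
        )
        shared = need + [rest_pool[i] for i in sorted(extra)]
        private = [
            f"{spec.cohort_id}_priv{i:05d}"
            for i in range(spec.n_genes - n_shared)
        ]
        genes = sorted(shared) + private
        mu = np.array([
            mu_global[g] if g in mu_global
            else crng.normal(BASELINE_MU, BASELINE_SD)
            for g in genes
        ])
        if spec.scale == "log_ratio":
            mu = mu - BASELINE_MU

        counts = _subtype_counts(spec)
        sample_ids: list[str] = []
        subtype_of: dict[str, str] = {}
        for t in sorted(counts):
            for i in range(counts[t]):
                sid = f"{spec.cohort_id}_{t}_{i:03d}"
                sample_ids.append(sid)
                subtype_of[sid] = t
        X = mu[:, None] + crng.normal(
            0.0, design.noise_sd, size=(len(genes), len(sample_ids))
        )
        if not design.null_mode:
            gene_pos = {g: i for i, g in enumerate(genes)}
            for p in design.programs:
                sign = 1.0 if p.direction == "up" else -1.0
                for cid, sub in p.members:
                    if cid != spec.cohort_id:
                        continue
                    cols = [
                        j for j, s in enumerate(sample_ids)
                        if subtype_of[s] == sub
                    ]
                    rows = [gene_pos[g] for g in p.genes]
                    X[np.ix_(rows, cols)] += sign * p.delta
        values = pd.DataFrame(X, index=genes, columns=sample_ids)
        cohorts.append(
            ExpressionCohort(spec.cohort_id, values, subtype_of,
                             scale=spec.scale)
        )

    partnerships = []
    for p in design.programs:
        for i, a in enumerate(p.members):
            for b in p.members[i + 1:]:
                if a[0] != b[0]:
                    partnerships.append(
                        {"program": p.name, "a": list(a), "b": list(b)}
                    )
    truth = {
        "null_mode": design.null_mode,
        "partnerships": partnerships if not design.null_mode else [],
        "programs": {
            p.name: {
                "genes": list(p.genes),
                "direction": p.direction,
                "delta": p.delta,
                "members": [list(m) for m in p.members],
            }
            for p in design.programs
        },
        "groups": (
            {f"{c}.{s}": g for (c, s), g in design.group_of.items()}
            if design.group_of else None
        ),
        "design": {
            "seed": design.seed,
            "noise_sd": design.noise_sd,
            "n_global_genes": design.n_global_genes,
            "cohorts": [asdict(c) for c in design.cohorts],
        },
    }
    return cohorts, truth


def hash_id(s: str) -> int:
    """Small deterministic integer from a string (stable across runs)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


def generate_gene_sets(
    design: SyntheticDesign,
    n_decoys: int = 30,
    set_size: int = 50,
) -> GeneSetCollection:
    """Planted modules as exact-membership sets plus random decoy sets.

    Decoys are drawn uniformly from the global universe and may overlap a
    planted module; the overlap count is recorded in the set description.
    """
    universe = global_universe(design.n_global_genes)
    if set_size > len(universe):
        raise DesignError("decoy set_size exceeds the global universe")
    rng = np.random.default_rng([design.seed, 3])
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    planted_genes: set[str] = set()
    for p in design.programs:
        if p.name in sets:
            # same module planted in both directions (two-group designs):
            # membership identical, keep one set entry
            continue
        sets[p.name] = frozenset(p.genes)
        descriptions[p.name] = f"planted|direction={p.direction}"
        planted_genes |= set(p.genes)
    for i in range(n_decoys):
        picks = rng.choice(len(universe), size=set_size, replace=False)
        genes = frozenset(universe[j] for j in picks)
        name = f"DECOY{i:04d}"
        sets[name] = genes
        descriptions[name] = (
            f"decoy|planted_overlap={len(genes & planted_genes)}"
        )
    return GeneSetCollection(sets, descriptions)
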