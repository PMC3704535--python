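"""Readers and writers for every external representation the pipeline touches.

Expression matrices arrive either as plain TSV (header row of sample ids,
first column of gene/probe ids) or as GCT v1.2 (``#1.2`` preamble, a
dimensions line, then the same layout with an extra Description column).
Gene sets use GMT semantics (one set per line: name, description, members).
Dendrograms are exported as rooted Newick with branch lengths taken from
merge-height differences.

Gene identifiers are matched by exact string equality throughout: the
pipeline expects identifiers already harmonized to a single namespace
(e.g. Entrez-centric symbols). Missing values are rejected rather than
imputed — a cell that does not parse as a finite number is a format error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, LabelError

logger = logging.getLogger(__name__)

#: float formatting used by every tabular writer; 10 significant digits keep
#: round-trips faithful at the precision the tests compare (6 significant
#: digits) while staying human-readable.
FLOAT_FORMAT = "%.10g"

SCALES = ("absolute", "log_ratio")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCohort:
    """One cohort's genes x samples expression matrix with subtype labels.

    Parameters
    ----------
    cohort_id
        Short identifier for the cohort (used in output keys).
    values
        Genes x samples :class:`pandas.DataFrame`; log2-scale expression for
        the ``absolute`` dialect, log2 ratio for the two-color ``log_ratio``
        dialect.
    subtype_of
        Mapping from sample id to molecular-subtype label. Every sample in
        the matrix must be labeled and every subtype must have at least two
        samples.
    scale
        ``"absolute"`` or ``"log_ratio"``; decides the GSEA ranking metric.
    """

    cohort_id: str
    values: pd.DataFrame
    subtype_of: dict[str, str]
    scale: str = "absolute"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise FormatError(
                f"cohort {self.cohort_id!r}: unknown scale {self.scale!r}; "
                f"expected one of {SCALES}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(
                f"cohort {self.cohort_id!r}: duplicate gene ids {dups[:5]}"
            )
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(
                f"cohort {self.cohort_id!r}: duplicate sample ids {dups[:5]}"
            )
        missing = [s for s in cols if s not in self.subtype_of]
        if missing:
            raise LabelError(
                f"cohort {self.cohort_id!r}: samples without a subtype "
                f"label: {missing[:5]}"
            )
        counts: dict[str, int] = {}
        for s in cols:
            counts[self.subtype_of[s]] = counts.get(self.subtype_of[s], 0) + 1
        small = [t for t, n in counts.items() if n < 2]
        if small:
            raise LabelError(
                f"cohort {self.cohort_id!r}: subtypes with fewer than two "
                f"samples: {small}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise FormatError(
                f"cohort {self.cohort_id!r}: matrix contains non-numeric or "
                "non-finite cells"
            )

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subtypes(self) -> list[str]:
        return sorted({self.subtype_of[s] for s in self.values.columns})

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s in self.values.columns if self.subtype_of[s] == subtype]

    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets over string gene identifiers (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, g in self.sets.items() if not g]
        if empty:
            raise FormatError(f"empty gene sets not allowed: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression matrices (TSV / GCT v1.2)
# ---------------------------------------------------------------------------

def _parse_matrix_lines(lines: list[str], path: str) -> pd.DataFrame:
    """Parse header + data lines shared by the TSV and GCT dialects."""
    if not lines:
        raise FormatError(f"{path}: empty matrix")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dup}")
    rows: list[str] = []
    data: list[list[float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{ln}: expected {len(sample_ids) + 1} fields, "
                f"got {len(parts)}"
            )
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric cell ({exc})") from exc
        if not all(math.isfinite(v) for v in vals):
            raise FormatError(f"{path}:{ln}: non-finite cell")
        rows.append(parts[0])
        data.append(vals)
    df = pd.DataFrame(data, index=rows, columns=sample_ids, dtype=float)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row ids {dup[:5]}")
    return df


def read_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes/probes x samples matrix from TSV or GCT v1.2.

    ``fmt`` may be ``"tsv"``, ``"gct"`` or ``None`` (sniffed from the
    ``#1.2`` preamble / file suffix).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if fmt is None:
        if lines and lines[0].startswith("#1.2"):
            fmt = "gct"
        elif path.suffix.lower() == ".gct":
            fmt = "gct"
        else:
            fmt = "tsv"
    if fmt == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise FormatError(f"{path}: not a GCT v1.2 file (missing '#1.2')")
        dims = lines[1].split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad GCT dimensions line") from exc
        body = lines[2:]
        # drop the Description column
        header = body[0].split("\t")
        if len(header) < 3 or header[1].lower() != "description":
            raise FormatError(f"{path}: GCT header lacks a Description column")
        stripped = []
        for line in body:
            parts = line.split("\t")
            stripped.append("\t".join(parts[:1] + parts[2:]))
        df = _parse_matrix_lines(stripped, str(path))
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: declared GCT dims {(n_genes, n_samples)} != "
                f"actual {df.shape}"
            )
        return df
    if fmt == "tsv":
        return _parse_matrix_lines(lines, str(path))
    raise FormatError(f"unknown expression format {fmt!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>subtype`` table (header optional)."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
        sample, subtype = parts[0], parts[1]
        if ln == 1 and sample.lower() in {"sample", "sample_id"}:
            continue
        if sample in out:
            raise FormatError(f"{path}:{ln}: duplicate sample {sample!r}")
        out[sample] = subtype
    return out


def read_expression(
    path: str | Path,
    *,
    labels: Mapping[str, str] | str | Path,
    scale: str = "absolute",
    cohort_id: str | None = None,
    fmt: str | None = None,
) -> ExpressionCohort:
    """Read and validate one cohort.

    ``labels`` is either an in-memory mapping or the path of a sidecar
    label table. A sample present in the matrix but absent from the labels
    raises :class:`LabelError`.
    """
    df = read_matrix(path, fmt=fmt)
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)
    cid = cohort_id if cohort_id is not None else Path(path).stem
    return ExpressionCohort(cid, df, dict(labels), scale=scale)


def write_matrix(
    df: pd.DataFrame, path: str | Path, fmt: str = "tsv"
) -> None:
    """Write a matrix as TSV (default) or GCT v1.2."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(map(str, df.columns)) + "\n")
            for gid, row in zip(df.index, df.to_numpy()):
                fh.write(
                    str(gid)
                    + "\t"
                    + "\t".join(FLOAT_FORMAT % v for v in row)
                    + "\n"
                )
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
            for gid, row in zip(df.index, df.to_numpy()):
                fh.write(
                    f"{gid}\tna\t"
                    + "\t".join(FLOAT_FORMAT % v for v in row)
                    + "\n"
                )
    else:
        raise FormatError(f"unknown expression format {fmt!r}")


def write_labels(subtype_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsubtype\n")
        for s in subtype_of:
            fh.write(f"{s}\t{subtype_of[s]}\n")


def write_expression(
    cohort: ExpressionCohort,
    path: str | Path,
    fmt: str = "tsv",
    labels_path: str | Path | None = None,
) -> None:
    write_matrix(cohort.values, path, fmt=fmt)
    if labels_path is not None:
        write_labels(cohort.subtype_of, labels_path)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is a format error; an empty file yields an empty
    collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{ln}: GMT line needs name, description and at "
                f"least one gene (got {len(parts)} fields)"
            )
        name, desc = parts[0], parts[1]
        if name in sets:
            raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{ln}: set {name!r} has no genes")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "na")
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

_NEWICK_SPECIALS = set("();:,'[] \t")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_SPECIALS for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree) -> str:
    """Serialize a merge tree as rooted Newick.

    ``tree`` must expose ``leaves`` (labels) and ``merges`` (sequence of
    ``(left, right, height)`` with scipy node numbering: leaf ``i`` < n,
    internal node ``n + step``). Branch length of every node is its parent's
    merge height minus its own height (leaves sit at height zero). The root
    carries no branch length.
    """
    leaves = list(tree.leaves)
    merges = list(tree.merges)
    n = len(leaves)
    if n == 0:
        raise FormatError("cannot serialize a tree with no leaves")
    for left, right, h in merges:
        if not math.isfinite(h):
            raise FormatError(f"non-finite merge height {h!r}")
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    rendered: dict[int, str] = {i: _newick_label(str(lbl)) for i, lbl in enumerate(leaves)}

    def _with_length(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        return f"{rendered[node]}:{bl:.6g}"

    for step, (left, right, h) in enumerate(merges):
        node = n + step
        height[node] = float(h)
        rendered[node] = f"({_with_length(left, h)},{_with_length(right, h)})"
    root = n + len(merges) - 1 if merges else 0
    return rendered[root] + ";"


def write_newick_file(tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# generic tabular output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with a header, deterministic formatting."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def iter_genes(collection: GeneSetCollection) -> Iterable[str]:
    for name in collection.names:
        yield from collection.sets[name]
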