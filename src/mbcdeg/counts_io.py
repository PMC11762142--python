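"""Reading, validating and writing RNA-seq count tables and DE result tables.

The on-disk count format is a plain tab-separated table: a header row of
sample identifiers (the first header field is ignored, conventionally
``gene_id``) followed by one row per gene whose first field is the gene
identifier and whose remaining fields are non-negative integer read counts.
Fractional or negative cells are rejected rather than rounded: the
downstream negative-binomial model is defined on integer counts, and silent
rounding would hide upstream processing mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "GroupDesign",
    "CountParseError",
    "read_counts",
    "write_counts",
    "design_from_labels",
    "write_results",
]


class CountParseError(ValueError):
    """Raised when a count table violates the expected format."""


@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Attributes
    ----------
    gene_ids :
        Unique gene identifiers, one per row, in file order.
    sample_ids :
        Unique sample identifiers, one per column, in file order.
    values :
        Integer array of shape ``(n_genes, n_samples)`` with all entries >= 0.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("count values must be a 2-D array")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise ValueError("counts must be integral (fractional input is rejected, not rounded)")
            vals = vals.astype(np.int64)
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "values", vals)
        G, J = vals.shape
        if G < 1:
            raise ValueError("count matrix needs at least one gene")
        if J < 2:
            raise ValueError("count matrix needs at least two samples")
        if len(self.gene_ids) != G:
            raise ValueError("gene_ids length does not match value rows")
        if len(self.sample_ids) != J:
            raise ValueError("sample_ids length does not match value columns")
        if len(set(self.gene_ids)) != G:
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != J:
            raise ValueError("sample identifiers must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GroupDesign:
    """Per-sample group labels for a between-group comparison.

    ``groups`` are the distinct labels in order of first appearance;
    ``replicate_counts`` holds the number of replicates per group.
    """

    labels: tuple
    groups: tuple = field(default=())
    replicate_counts: tuple = field(default=())

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        groups = []
        for lab in labels:
            if lab not in groups:
                groups.append(lab)
        groups = tuple(groups)
        counts = tuple(sum(1 for lab in labels if lab == g) for g in groups)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "replicate_counts", counts)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def group_index(self) -> np.ndarray:
        """Index of each sample's group within ``groups`` (length J)."""
        lookup = {g: i for i, g in enumerate(self.groups)}
        return np.array([lookup[lab] for lab in self.labels], dtype=np.intp)

    def members(self, i: int) -> np.ndarray:
        """Column indices of the samples belonging to group ``i``."""
        return np.flatnonzero(self.group_index == i)


def design_from_labels(labels) -> GroupDesign:
    """Build a :class:`GroupDesign` from a per-sample label sequence.

    Groups are ordered by first appearance. At least two distinct labels are
    required: a single group admits no between-group contrast.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two samples")
    design = GroupDesign(tuple(labels))
    if design.n_groups < 2:
        raise ValueError("DE analysis requires >=2 groups")
    return design


def read_counts(path) -> CountMatrix:
    """Read and validate a tab-separated count table.

    Raises :class:`CountParseError` naming the offending row/column for
    malformed headers, non-integer or negative cells, and duplicate
    identifiers. Row and column order are preserved as-is.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CountParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise CountParseError(f"{path}: header must contain at least two sample columns")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise CountParseError(f"{path}: duplicate sample identifier {dup!r} in header")
    gene_ids = []
    rows = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise CountParseError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        gid = cells[0]
        if gid in seen:
            raise CountParseError(f"{path}: duplicate gene identifier {gid!r} at line {lineno}")
        seen.add(gid)
        row = []
        for colno, cell in enumerate(cells[1:]):
            try:
                v = int(cell)
            except ValueError:
                raise CountParseError(
                    f"{path}: cell {cell!r} at line {lineno}, column {sample_ids[colno]!r} "
                    "is not a non-negative integer"
                ) from None
            if v < 0:
                raise CountParseError(
                    f"{path}: cell {cell!r} at line {lineno}, column {sample_ids[colno]!r} "
                    "is negative"
                )
            row.append(v)
        gene_ids.append(gid)
        rows.append(row)
    if not rows:
        raise CountParseError(f"{path}: no data rows")
    return CountMatrix(tuple(gene_ids), tuple(sample_ids), np.array(rows, dtype=np.int64))


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix in the canonical tab-separated format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for gid, row in zip(cm.gene_ids, cm.values):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_results(result, model, path) -> None:
    """Write a ranked DE result table (one row per gene).

    Columns: ``gene_id``, ``cluster`` (1-based argmax-posterior cluster),
    ``pp_nondeg`` (posterior probability in the non-DEG cluster; lower =
    more differentially expressed), ``rank`` (1 = most DE) and ``pattern``.
    """
    gene_ids = getattr(result, "gene_ids", None)
    if gene_ids is None:
        gene_ids = [f"gene_{i + 1}" for i in range(len(result.scores))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcluster\tpp_nondeg\trank\tpattern\n")
        for gid, cl, score, rank, pat in zip(
            gene_ids, result.cluster_assignment, result.scores, result.ranks, result.patterns
        ):
            fh.write(f"{gid}\t{int(cl)}\t{score:.10g}\t{int(rank)}\t{pat}\n")
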