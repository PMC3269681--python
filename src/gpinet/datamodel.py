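"""Domain types and I/O for combined gene-expression / morphology matrices.

The learner operates on a single node-by-sample matrix whose rows are
gene-expression nodes, neuronal-morphology nodes, and (optionally) an
exposure-dose node, and whose columns are samples tagged with an exposure
condition.  This module owns that container (:class:`SampleMatrix`), the
TSV dialect it is stored in, gene-set subsetting, and the raw→log-space
transform the log-linear model requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeDescriptor",
    "SampleMatrix",
    "GeneSet",
    "MatrixFormatError",
    "AlignmentError",
    "SelectionError",
    "NODE_KINDS",
    "PHENOTYPE_NODES",
    "read_sample_matrix",
    "write_sample_matrix",
    "combine",
    "subset_by_gene_set",
    "to_log_space",
    "aggregate_condition_means",
    "read_gmt",
    "table2_gene_sets",
    "make_phenotype_nodes",
]

log = logging.getLogger(__name__)

NODE_KINDS = ("gene", "phenotype", "dose")

#: The ten high-content imaging parameters measured on differentiated
#: neuronal cultures: nucleus counts/areas, neurosphere geometry, and
#: neurite outgrowth statistics.
PHENOTYPE_NODES: tuple[tuple[str, str], ...] = (
    ("Nuc_count", "number of all cells (nuclei)"),
    ("Nuc_area", "nucleus area"),
    ("NS_count", "number of neurospheres"),
    ("NS_area", "neurosphere area"),
    ("NS_perimeter", "neurosphere perimeter"),
    ("NS_formfactor", "neurosphere form factor"),
    ("posi_area", "area of neural-marker-positive cells"),
    ("Neurite_length", "total neurite length per cell"),
    ("Branch_point", "neurite branch points"),
    ("Crossing_point", "neurite crossing points"),
)

_CONDITION_ROW = "#condition"


class MatrixFormatError(ValueError):
    """Malformed matrix file or invalid matrix contents."""


class AlignmentError(ValueError):
    """Sample axes of two matrices do not line up."""


class SelectionError(ValueError):
    """A subset operation selected too few nodes."""


@dataclass(frozen=True)
class NodeDescriptor:
    """Identity of one network node: a gene, a morphology parameter, or dose."""

    name: str
    kind: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise MatrixFormatError("node name must be non-empty")
        if self.kind not in NODE_KINDS:
            raise MatrixFormatError(
                f"node {self.name!r}: kind {self.kind!r} not one of {NODE_KINDS}"
            )


@dataclass
class SampleMatrix:
    """Node-by-sample data matrix with per-sample condition labels.

    Node order is frozen at construction and is the single source of the
    node index used by every downstream structure/posterior object.

    Parameters
    ----------
    nodes
        Ordered node descriptors (length P).
    values
        P x N array.  Positive in ``raw`` space; any finite value in
        ``log`` space.
    sample_ids
        Unique sample identifiers (length N).
    condition
        Condition label per sample (length N); opaque strings.
    space
        ``"raw"`` for measured intensities, ``"log"`` after the natural-log
        transform.
    n_floored
        Number of cells clipped to the floor during the log transform.
    """

    nodes: list[NodeDescriptor]
    values: np.ndarray
    sample_ids: list[str]
    condition: list[str]
    space: str = "raw"
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        P, N = self.values.shape
        if P != len(self.nodes):
            raise MatrixFormatError("values row count does not match node count")
        if N != len(self.sample_ids) or N != len(self.condition):
            raise MatrixFormatError("values column count does not match sample axis")
        if P < 2:
            raise MatrixFormatError(f"need at least 2 nodes, got {P}")
        if N < 3:
            raise MatrixFormatError(f"need at least 3 samples, got {N}")
        if self.space not in ("raw", "log"):
            raise MatrixFormatError(f"unknown space {self.space!r}")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MatrixFormatError(f"duplicate node names: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixFormatError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixFormatError(
                f"non-finite value at node {names[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.space == "raw" and np.any(self.values <= 0):
            bad = np.argwhere(self.values <= 0)[0]
            raise MatrixFormatError(
                f"non-positive value at node {names[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}: raw values must be > 0 "
                "so natural logs exist"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def index_of(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"no node named {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols (one analysis's gene nodes)."""

    name: str
    symbols: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        lowered = [s.strip().lower() for s in self.symbols]
        if len(set(lowered)) != len(lowered):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_sample_matrix(path, kind_map: Mapping[str, str]) -> SampleMatrix:
    """Read a node-by-sample TSV into a raw-space :class:`SampleMatrix`.

    Dialect: UTF-8 tab-separated; row 1 is the header of sample IDs, row 2
    (index cell ``#condition``) holds per-sample condition labels, every
    later row is one node.  ``kind_map`` must assign a kind to every node
    name in the file; file row order becomes the canonical node order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] < 1 or df.index[0] != _CONDITION_ROW:
        raise MatrixFormatError(
            f"{path}: second row must carry condition labels "
            f"(first column cell {_CONDITION_ROW!r})"
        )
    condition = [str(c) for c in df.iloc[0]]
    body = df.iloc[1:]
    sample_ids = [str(c) for c in df.columns]
    names = [str(i) for i in body.index]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise MatrixFormatError(f"{path}: duplicate node row(s) {dupes}")
    missing = [n for n in names if n not in kind_map]
    if missing:
        raise MatrixFormatError(f"{path}: no kind given for node(s) {missing}")
    values = np.empty((len(names), len(sample_ids)), dtype=float)
    for r, name in enumerate(names):
        for c, sid in enumerate(sample_ids):
            cell = body.iat[r, c]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at node {name!r}, "
                    f"sample {sid!r}"
                ) from None
            values[r, c] = v
    nodes = [NodeDescriptor(n, kind_map[n]) for n in names]
    return SampleMatrix(nodes, values, sample_ids, condition, space="raw")


def write_sample_matrix(matrix: SampleMatrix, path) -> None:
    """Write the canonical TSV dialect (read→write→read round-trips)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write(_CONDITION_ROW + "\t" + "\t".join(matrix.condition) + "\n")
        for node, row in zip(matrix.nodes, matrix.values):
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{node.name}\t{cells}\n")


# ---------------------------------------------------------------------------
# Matrix algebra on the sample axis
# ---------------------------------------------------------------------------

def combine(
    expression: SampleMatrix,
    phenotype: SampleMatrix,
    dose: SampleMatrix | None = None,
) -> SampleMatrix:
    """Row-concatenate expression, phenotype and (optionally) dose matrices.

    All inputs must share the same sample IDs, condition labels, sample
    order and value space; node names must be globally unique.
    """
    parts = [expression, phenotype] + ([dose] if dose is not None else [])
    ref = parts[0]
    for other in parts[1:]:
        if other.sample_ids != ref.sample_ids:
            raise AlignmentError(
                "sample IDs differ between inputs (count, identity or order)"
            )
        if other.condition != ref.condition:
            raise AlignmentError("condition labels differ between inputs")
        if other.space != ref.space:
            raise AlignmentError(
                f"cannot combine {ref.space}-space with {other.space}-space data"
            )
    all_names = [n.name for part in parts for n in part.nodes]
    if len(set(all_names)) != len(all_names):
        dupes = sorted({n for n in all_names if all_names.count(n) > 1})
        raise AlignmentError(f"duplicate node names across inputs: {dupes}")
    return SampleMatrix(
        nodes=[n for part in parts for n in part.nodes],
        values=np.vstack([part.values for part in parts]),
        sample_ids=list(ref.sample_ids),
        condition=list(ref.condition),
        space=ref.space,
        n_floored=sum(part.n_floored for part in parts),
    )


def subset_by_gene_set(
    matrix: SampleMatrix,
    gene_set: GeneSet,
    keep_kinds: Iterable[str] = ("phenotype", "dose"),
) -> tuple[SampleMatrix, list[str]]:
    """Restrict gene nodes to one gene set, keeping non-gene kinds.

    Matching is case-insensitive exact symbol match after whitespace
    trimming; no alias resolution.  Returns the subset matrix (original
    node order preserved) and the list of set symbols with no matching
    node.
    """
    keep_kinds = frozenset(keep_kinds)
    wanted = {s.strip().lower() for s in gene_set.symbols}
    keep_idx = [
        i
        for i, node in enumerate(matrix.nodes)
        if (node.kind == "gene" and node.name.strip().lower() in wanted)
        or (node.kind != "gene" and node.kind in keep_kinds)
    ]
    matched = {
        matrix.nodes[i].name.strip().lower()
        for i in keep_idx
        if matrix.nodes[i].kind == "gene"
    }
    unmatched = [s for s in gene_set.symbols if s.strip().lower() not in matched]
    if len(keep_idx) < 2:
        raise SelectionError(
            f"gene set {gene_set.name!r} with keep_kinds={sorted(keep_kinds)} "
            f"selects {len(keep_idx)} node(s); at least 2 required"
        )
    if unmatched:
        log.info(
            "gene set %s: %d symbol(s) with no matching node: %s",
            gene_set.name, len(unmatched), ", ".join(unmatched),
        )
    sub = SampleMatrix(
        nodes=[matrix.nodes[i] for i in keep_idx],
        values=matrix.values[keep_idx],
        sample_ids=list(matrix.sample_ids),
        condition=list(matrix.condition),
        space=matrix.space,
        n_floored=matrix.n_floored,
    )
    return sub, unmatched


def to_log_space(matrix: SampleMatrix, floor: float = 1e-6) -> SampleMatrix:
    """Natural-log transform: value → ln(max(value, floor)).

    The model assumes node logs are conditionally Gaussian, so the learner
    consumes log-space matrices only.  Values at or below ``floor`` are
    clipped (not dropped) and counted in ``n_floored``.
    """
    if matrix.space == "log":
        raise MatrixFormatError("matrix already in log space; refusing to re-log")
    if floor <= 0:
        raise ValueError("floor must be positive")
    clipped = np.maximum(matrix.values, floor)
    n_floored = int(np.sum(matrix.values < floor))
    if n_floored:
        log.info("log transform floored %d cell(s) at %g", n_floored, floor)
    return replace(
        matrix,
        nodes=list(matrix.nodes),
        values=np.log(clipped),
        sample_ids=list(matrix.sample_ids),
        condition=list(matrix.condition),
        space="log",
        n_floored=matrix.n_floored + n_floored,
    )


def aggregate_condition_means(matrix: SampleMatrix) -> SampleMatrix:
    """Collapse samples to one per-condition mean column.

    Explicit fallback for study designs where expression and morphology
    were measured on different numbers of replicates: aggregate each block
    to condition means first, then :func:`combine`.  The aggregation is
    logged because it discards within-condition variation.
    """
    conds = list(dict.fromkeys(matrix.condition))  # first-appearance order
    if len(conds) < 3:
        raise AlignmentError(
            f"mean aggregation needs >= 3 conditions, got {len(conds)}"
        )
    cond_arr = np.asarray(matrix.condition)
    means = np.column_stack(
        [matrix.values[:, cond_arr == c].mean(axis=1) for c in conds]
    )
    log.warning(
        "aggregated %d samples to %d per-condition means; within-condition "
        "variation discarded", matrix.n_samples, len(conds),
    )
    return SampleMatrix(
        nodes=list(matrix.nodes),
        values=means,
        sample_ids=list(conds),
        condition=list(conds),
        space=matrix.space,
        n_floored=matrix.n_floored,
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read GMT-style gene sets: name TAB description TAB symbol TAB ..."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one symbol"
                )
            name, desc, *symbols = fields
            symbols = [s for s in symbols if s.strip()]
            sets.append(GeneSet(name=name, symbols=tuple(symbols), description=desc))
    return sets


def table2_gene_sets() -> dict[str, GeneSet]:
    """The seven packaged neural-development / disease gene sets."""
    ref = resources.files("gpinet.data") / "gene_sets.gmt"
    with resources.as_file(ref) as path:
        return {gs.name: gs for gs in read_gmt(path)}


def make_phenotype_nodes() -> list[NodeDescriptor]:
    """Descriptors for the ten high-content morphology parameters."""
    return [NodeDescriptor(n, "phenotype", d) for n, d in PHENOTYPE_NODES]
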