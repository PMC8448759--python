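"""Sparse connectivity construction from biological annotation tables.

A network architecture in this package is fully determined by a stack of
:class:`ConnectivityMatrix` objects: sparse binary maps between two ordered
node sets (variants to genes, genes to pathways, genes to tissues, ...).
Every learnable weight in the downstream network corresponds to exactly one
link in one of these matrices, which is what makes each node identifiable
with a biological entity.

Builders in this module consume plain annotation tables (two-column child /
parent TSVs, or gene-by-tissue t-score TSVs) and produce validated matrices
with deterministic (lexicographic) node orderings plus a report of anything
that was dropped: unannotated variants, genes with no pathway, outputs left
without links after masking.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ANNOTATION_KINDS = ("snp_gene", "gene_exon_gene", "gene_pathway_level")


class AnnotationError(ValueError):
    """Raised when an annotation table or connectivity stack is invalid."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Sparse binary map between two ordered node sets.

    Parameters
    ----------
    input_names, output_names
        Ordered, duplicate-free node identifiers for the two sides.
    row, col
        Parallel integer arrays: link k connects ``input_names[row[k]]`` to
        ``output_names[col[k]]``. Links are canonicalised to (row, col) order
        and must be unique.
    level_label
        Free-text description of the level, e.g. ``"SNP->gene"``.
    """

    input_names: tuple
    output_names: tuple
    row: np.ndarray
    col: np.ndarray
    level_label: str = ""

    def __post_init__(self):
        inames = tuple(str(n) for n in self.input_names)
        onames = tuple(str(n) for n in self.output_names)
        if len(set(inames)) != len(inames):
            raise AnnotationError("duplicate input node identifiers")
        if len(set(onames)) != len(onames):
            raise AnnotationError("duplicate output node identifiers")
        row = np.asarray(self.row, dtype=np.int64)
        col = np.asarray(self.col, dtype=np.int64)
        if row.shape != col.shape or row.ndim != 1:
            raise AnnotationError("row/col must be parallel 1-d arrays")
        if row.size:
            if row.min() < 0 or row.max() >= len(inames):
                raise AnnotationError("link input index out of range")
            if col.min() < 0 or col.max() >= len(onames):
                raise AnnotationError("link output index out of range")
        # canonical order: sort by (row, col); duplicates are an error
        key = row * max(len(onames), 1) + col
        order = np.argsort(key, kind="stable")
        key = key[order]
        if key.size and np.any(np.diff(key) == 0):
            raise AnnotationError("duplicate links")
        object.__setattr__(self, "input_names", inames)
        object.__setattr__(self, "output_names", onames)
        object.__setattr__(self, "row", row[order])
        object.__setattr__(self, "col", col[order])
        self.row.setflags(write=False)
        self.col.setflags(write=False)

    # -- basic queries ----------------------------------------------------
    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    @property
    def n_links(self) -> int:
        return int(self.row.size)

    @property
    def links(self) -> frozenset:
        return frozenset(zip(self.row.tolist(), self.col.tolist()))

    @property
    def density(self) -> float:
        denom = self.n_inputs * self.n_outputs
        return self.n_links / denom if denom else 0.0

    def zero_link_outputs(self) -> tuple:
        """Output node ids with no incoming link."""
        deg = np.bincount(self.col, minlength=self.n_outputs)
        return tuple(self.output_names[j] for j in np.flatnonzero(deg == 0))

    def to_sparse(self, data: np.ndarray | None = None) -> sp.csr_matrix:
        """CSR matrix of shape (n_inputs, n_outputs); ``data`` defaults to 1s.

        When ``data`` is given it must be aligned with the canonical link
        order of this matrix.
        """
        if data is None:
            data = np.ones(self.n_links)
        return sp.csr_matrix(
            (np.asarray(data, dtype=float), (self.row, self.col)),
            shape=(self.n_inputs, self.n_outputs),
        )

    # -- interchange format ----------------------------------------------
    def write(self, prefix: str | Path) -> None:
        """Write links to ``<prefix>.tsv`` and node orders to ``<prefix>.json``."""
        prefix = str(prefix)
        with open(prefix + ".tsv", "w") as fh:
            fh.write("child\tparent\tlevel_label\n")
            for i, j in zip(self.row, self.col):
                fh.write(
                    f"{self.input_names[i]}\t{self.output_names[j]}\t{self.level_label}\n"
                )
        sidecar = {
            "input_names": list(self.input_names),
            "output_names": list(self.output_names),
            "level_label": self.level_label,
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def read(cls, prefix: str | Path) -> "ConnectivityMatrix":
        prefix = str(prefix)
        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        links = pd.read_csv(prefix + ".tsv", sep="\t", dtype=str)
        iidx = {n: i for i, n in enumerate(sidecar["input_names"])}
        oidx = {n: j for j, n in enumerate(sidecar["output_names"])}
        row = np.array([iidx[c] for c in links["child"]], dtype=np.int64)
        col = np.array([oidx[p] for p in links["parent"]], dtype=np.int64)
        return cls(
            tuple(sidecar["input_names"]),
            tuple(sidecar["output_names"]),
            row,
            col,
            sidecar["level_label"],
        )


@dataclass
class AnnotationTable:
    """Two-column (child_id, parent_id) annotation; duplicate rows collapse."""

    pairs: pd.DataFrame  # columns: child, parent
    kind: str = "snp_gene"

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise AnnotationError(f"unknown annotation kind {self.kind!r}")
        df = self.pairs[["child", "parent"]].astype(str)
        df = df.apply(lambda s: s.str.strip())
        if (df["child"] == "").any() or (df["parent"] == "").any():
            raise AnnotationError("empty identifiers in annotation table")
        self.pairs = df.drop_duplicates(ignore_index=True)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], kind: str = "snp_gene"):
        df = pd.DataFrame(list(pairs), columns=["child", "parent"])
        return cls(df, kind)

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "snp_gene"):
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        return cls(df.rename(columns={df.columns[0]: "child", df.columns[1]: "parent"}), kind)

    @property
    def children(self) -> set:
        return set(self.pairs["child"])

    @property
    def parents(self) -> set:
        return set(self.pairs["parent"])


@dataclass
class ExpressionTable:
    """Gene-by-tissue t-score table (group-wise differential-expression scores)."""

    scores: pd.DataFrame  # index: gene_id, columns: tissue names, float t-scores

    MIN_GENES_PER_TISSUE = 10

    def __post_init__(self):
        df = self.scores.astype(float)
        df.index = df.index.astype(str)
        if not np.isfinite(df.to_numpy()).all():
            raise AnnotationError("non-finite t-scores in expression table")
        if df.index.duplicated().any():
            raise AnnotationError("duplicate gene ids in expression table")
        short = [c for c in df.columns if df[c].count() < self.MIN_GENES_PER_TISSUE]
        if short:
            raise AnnotationError(
                f"tissue columns with fewer than {self.MIN_GENES_PER_TISSUE} genes: {short}"
            )
        self.scores = df

    @classmethod
    def from_tsv(cls, path: str | Path):
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class BuildReport:
    """What a builder dropped or flagged, so nothing disappears silently."""

    dropped_inputs: tuple = ()
    uncovered: tuple = ()
    zero_link_outputs: tuple = ()
    masked_links: int = 0
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_snp_gene_matrix(
    table: AnnotationTable,
    variant_order: Sequence[str],
    keep_unannotated: bool = False,
) -> tuple[ConnectivityMatrix, BuildReport]:
    """Connect variants to their annotated genes.

    ``variant_order`` fixes the input ordering (it must match the column order
    of the genotype matrix). Gene order is lexicographic. Variants absent from
    the table are dropped from the inputs and listed in the report, unless
    ``keep_unannotated`` keeps them as zero-link inputs (useful when the
    genotype matrix must not be re-cut).
    """
    if table.kind != "snp_gene":
        raise AnnotationError(f"expected a snp_gene table, got {table.kind!r}")
    variant_order = [str(v) for v in variant_order]
    vset = set(variant_order)
    if len(vset) != len(variant_order):
        raise AnnotationError("duplicate variant ids in variant_order")
    pairs = table.pairs[table.pairs["child"].isin(vset)]
    if pairs.empty:
        raise AnnotationError(
            f"no overlap between annotation table ({len(table.children)} variants) "
            f"and variant_order ({len(variant_order)} variants)"
        )
    annotated = set(pairs["child"])
    dropped = tuple(v for v in variant_order if v not in annotated)
    inputs = variant_order if keep_unannotated else [v for v in variant_order if v in annotated]
    genes = sorted(set(pairs["parent"]))
    iidx = {v: i for i, v in enumerate(inputs)}
    gidx = {g: j for j, g in enumerate(genes)}
    row = pairs["child"].map(iidx).to_numpy(dtype=np.int64)
    col = pairs["parent"].map(gidx).to_numpy(dtype=np.int64)
    cm = ConnectivityMatrix(tuple(inputs), tuple(genes), row, col, "SNP->gene")
    if dropped:
        logger.info("build_snp_gene_matrix: %d unannotated variants %s",
                    len(dropped), "kept as zero-link inputs" if keep_unannotated else "dropped")
    return cm, BuildReport(dropped_inputs=dropped)


def build_pathway_stack(
    tables: Sequence[AnnotationTable],
    gene_order: Sequence[str] | None = None,
) -> tuple[list[ConnectivityMatrix], BuildReport]:
    """Build a chained hierarchy of connectivity matrices (e.g. KEGG 3-level).

    ``tables`` are ordered bottom-up: gene->local, local->mid, mid->global.
    Output node order of matrix k equals input node order of matrix k+1, so
    the matrices can be stacked directly into a network. If ``gene_order`` is
    given, level-0 inputs are restricted to (and ordered by) it; genes with no
    pathway are reported as uncovered.
    """
    if not tables:
        raise AnnotationError("empty table list")
    uncovered: tuple = ()
    t0 = tables[0]
    if gene_order is not None:
        gene_order = [str(g) for g in gene_order]
        covered = t0.children
        uncovered = tuple(g for g in gene_order if g not in covered)
        inputs = [g for g in gene_order if g in covered]
        pairs0 = t0.pairs[t0.pairs["child"].isin(set(inputs))]
        if pairs0.empty:
            raise AnnotationError("no gene in gene_order has a pathway annotation")
    else:
        inputs = sorted(t0.children)
        pairs0 = t0.pairs

    matrices: list[ConnectivityMatrix] = []
    level_inputs = inputs
    pairs = pairs0
    for k, table in enumerate(tables):
        if k > 0:
            extra = table.children - set(level_inputs)
            if extra:
                raise AnnotationError(
                    f"level {k} children not present among level {k - 1} parents: {sorted(extra)}"
                )
            pairs = table.pairs
        outputs = sorted(set(pairs["parent"]))
        iidx = {n: i for i, n in enumerate(level_inputs)}
        oidx = {n: j for j, n in enumerate(outputs)}
        sub = pairs[pairs["child"].isin(iidx)]
        row = sub["child"].map(iidx).to_numpy(dtype=np.int64)
        col = sub["parent"].map(oidx).to_numpy(dtype=np.int64)
        label = f"level{k}->level{k + 1}"
        matrices.append(
            ConnectivityMatrix(tuple(level_inputs), tuple(outputs), row, col, label)
        )
        if k + 1 < len(tables):
            orphans = set(outputs) - tables[k + 1].children
            if orphans:
                raise AnnotationError(
                    f"level {k + 1} nodes with no parent at level {k + 2}: {sorted(orphans)}"
                )
        level_inputs = outputs
    return matrices, BuildReport(uncovered=uncovered)


def build_expression_matrix(
    expr: ExpressionTable,
    top_fraction: float = 0.10,
) -> tuple[ConnectivityMatrix, BuildReport]:
    """Connect each tissue to the genes with the top-fraction highest t-scores.

    Per tissue exactly ``ceil(top_fraction * n_genes)`` genes are linked;
    ties at the boundary break lexicographically (smaller gene id included).
    The default 0.10 keeps the top 10% of genes per tissue, which keeps nodes
    distinguishable by their connections.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise AnnotationError("top_fraction must be in (0, 1]")
    genes = sorted(expr.scores.index)
    tissues = sorted(expr.scores.columns.astype(str))
    n_top = math.ceil(top_fraction * len(genes))
    gidx = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for j, tissue in enumerate(tissues):
        s = expr.scores[tissue]
        ranked = sorted(s.index, key=lambda g: (-s[g], g))
        for g in ranked[:n_top]:
            rows.append(gidx[g])
            cols.append(j)
    cm = ConnectivityMatrix(
        tuple(genes), tuple(tissues),
        np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64),
        "gene->tissue",
    )
    linked = set(cm.row.tolist())
    unlinked = tuple(genes[i] for i in range(len(genes)) if i not in linked)
    return cm, BuildReport(notes=[f"{len(unlinked)} genes linked to no tissue"])


def apply_mask(
    cm: ConnectivityMatrix, masked_inputs: Iterable[str]
) -> tuple[ConnectivityMatrix, BuildReport]:
    """Remove all links from the given inputs, keeping input positions intact.

    Input order is preserved so the genotype matrix does not need re-cutting;
    outputs that lose all links are flagged in the report.
    """
    masked = {str(m) for m in masked_inputs}
    unknown = masked - set(cm.input_names)
    if unknown:
        raise AnnotationError(f"masked ids not among inputs: {sorted(unknown)}")
    midx = {i for i, n in enumerate(cm.input_names) if n in masked}
    keep = np.array([r not in midx for r in cm.row], dtype=bool)
    out = ConnectivityMatrix(
        cm.input_names, cm.output_names, cm.row[keep], cm.col[keep], cm.level_label
    )
    n_removed = int((~keep).sum())
    logger.info("apply_mask: removed %d links from %d masked inputs", n_removed, len(masked))
    return out, BuildReport(
        masked_links=n_removed, zero_link_outputs=out.zero_link_outputs()
    )


@dataclass
class StackReport:
    layers: list
    warnings: list
    ok: bool = True


def validate_stack(matrices: Sequence[ConnectivityMatrix]) -> StackReport:
    """Check that matrices chain and that outputs are uniquely defined.

    Chaining: output names of matrix k must equal input names of matrix k+1
    (order included). Two outputs of the same matrix with identical link sets
    are not distinguishable by their connections and trigger a warning naming
    both. Returns per-layer node and link counts.
    """
    if not matrices:
        raise AnnotationError("empty stack")
    warnings: list[str] = []
    layers = []
    for k, cm in enumerate(matrices):
        if k + 1 < len(matrices):
            nxt = matrices[k + 1]
            if cm.output_names != nxt.input_names:
                raise AnnotationError(
                    f"chaining violation between matrix {k} ({cm.level_label!r}) and "
                    f"matrix {k + 1} ({nxt.level_label!r}): output/input node orders differ"
                )
        sig: dict[frozenset, str] = {}
        for j in range(cm.n_outputs):
            s = frozenset(cm.row[cm.col == j].tolist())
            if s in sig:
                warnings.append(
                    f"matrix {k}: outputs {sig[s]!r} and {cm.output_names[j]!r} "
                    "have identical link sets"
                )
            else:
                sig[s] = cm.output_names[j]
        zero = cm.zero_link_outputs()
        if zero:
            warnings.append(f"matrix {k}: zero-link outputs {list(zero)}")
        layers.append(
            {"level_label": cm.level_label, "n_inputs": cm.n_inputs,
             "n_outputs": cm.n_outputs, "n_links": cm.n_links}
        )
    return StackReport(layers=layers, warnings=warnings, ok=not warnings)
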