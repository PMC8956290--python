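"""Standard-format I/O: 10x-style MTX triplets, cell metadata tables, GMT sets.

The on-disk layout mirrors the 10x Genomics convention: ``matrix.mtx``
(Matrix Market coordinate, genes x cells), ``genes.tsv`` and ``barcodes.tsv``,
plus a ``cells.tsv`` metadata table (age, batch, and, for synthetic data,
ground-truth columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse genes x cells integer transcript counts with identifiers.

    ``obs`` holds per-cell metadata (at least ``age`` and ``batch``) indexed
    like ``cells``.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique or not self.cells.is_unique:
            raise ValueError("gene and cell identifiers must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.obs is None:
            self.obs = pd.DataFrame(index=self.cells)
        else:
            self.obs = self.obs.set_axis(self.cells, axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(len(self.genes), bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(len(self.cells), bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            genes=self.genes[gm],
            cells=self.cells[cm],
            obs=self.obs.loc[cm],
        )


@dataclass
class ExpressionMatrix:
    """Genes x cells normalized log expression with the normalization target."""

    X: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    target: float
    obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.obs is None:
            self.obs = pd.DataFrame(index=self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def subset_genes(self, gene_names) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_names))
        if (idx < 0).any():
            missing = pd.Index(gene_names)[idx < 0]
            raise KeyError(f"genes not in matrix: {list(missing[:5])} ...")
        return ExpressionMatrix(
            X=self.X[idx], genes=self.genes[idx], cells=self.cells,
            target=self.target, obs=self.obs,
        )


def write_10x(outdir: str | Path, cm: CountMatrix) -> None:
    """Write ``matrix.mtx`` / ``genes.tsv`` / ``barcodes.tsv`` / ``cells.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(cm.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cells).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    cm.obs.rename_axis("cell").reset_index().to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_10x(indir: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory (plus ``cells.tsv`` if present)."""
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = None
    if (indir / "cells.tsv").exists():
        obs = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell")
    return CountMatrix(counts=counts, genes=pd.Index(genes), cells=pd.Index(cells), obs=obs)


def write_gmt(path: str | Path, sets: dict[str, list[str]], description: str = "") -> None:
    """Write named member sets (marker genes or cell sets) in GMT format."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description or name, *map(str, members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets
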