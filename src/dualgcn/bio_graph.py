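"""Biological graph construction: cancer-gene PPI adjacency and per-sample
2-channel node features (expression, copy number).

The node set is a fixed, ordered cancer-related gene list; the adjacency is
shared across samples while each sample contributes its own feature matrix.
Feature channels can be masked for ablation (expression-only / CNV-only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_BIO_CHANNELS = 2  # column 0 = expression, column 1 = CNV


@dataclass
class PPINetwork:
    """Ordered gene list with its symmetric binary interaction adjacency."""

    genes: list[str]
    A_b: np.ndarray = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.A_b.sum()) // 2

    def validate(self) -> None:
        if self.A_b.shape != (self.n_genes, self.n_genes):
            raise ValueError("adjacency shape does not match gene list")
        if not np.array_equal(self.A_b, self.A_b.T):
            raise ValueError("PPI adjacency must be symmetric")
        if np.any(np.diagonal(self.A_b) != 0):
            raise ValueError("PPI adjacency must have a zero diagonal")


@dataclass
class BioGraph:
    """One sample's node features over the shared PPI node order."""

    sample_id: str
    X_raw: np.ndarray = field(repr=False)
    feature_mask: tuple[int, int] = (1, 1)


def build_ppi_adjacency(edges: Iterable[tuple[str, str, float]],
                        gene_list: Sequence[str],
                        min_score: float = 700.0) -> PPINetwork:
    """Build the PPI adjacency over ``gene_list`` from a scored edge list.

    Keeps edges whose endpoints are both in the gene list and whose combined
    score is at least ``min_score``; symmetrizes, drops self-edges and
    duplicates. Genes touched by no kept edge remain as isolated nodes.
    """
    genes = list(gene_list)
    if not genes:
        raise ValueError("gene_list must not be empty")
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ValueError(f"duplicate genes in gene_list: {sorted(dupes)}")
    index = {g: k for k, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for g1, g2, score in edges:
        if score < min_score or g1 == g2:
            continue
        k, m = index.get(g1), index.get(g2)
        if k is None or m is None:
            continue
        A[k, m] = A[m, k] = 1
    net = PPINetwork(genes=genes, A_b=A)
    net.validate()
    return net


def read_ppi_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a STRING-style TSV: columns protein1, protein2, combined_score."""
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        c1, c2, cs = (header.index(name) for name in
                      ("protein1", "protein2", "combined_score"))
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            edges.append((f[c1], f[c2], float(f[cs])))
    return edges


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


def assemble_bio_graph(expr: Mapping[str, float], cnv: Mapping[str, float],
                       network: PPINetwork,
                       feature_mask: tuple[int, int] = (1, 1),
                       sample_id: str = "") -> BioGraph:
    """Stack per-gene expression and CNV into the network's node order.

    ``feature_mask`` zeroes whole channels for ablation: (1,0) keeps only
    expression, (0,1) only CNV. Genes missing from a map impute to 0 (the
    population mean on the z-score scale) with a logged warning.
    """
    if feature_mask == (0, 0):
        raise ValueError("feature_mask (0,0) would zero both channels")
    X = np.zeros((network.n_genes, N_BIO_CHANNELS))
    missing: list[str] = []
    for k, gene in enumerate(network.genes):
        for c, source in enumerate((expr, cnv)):
            if gene in source:
                X[k, c] = source[gene]
            else:
                missing.append(f"{gene}/{'expr' if c == 0 else 'cnv'}")
    if missing:
        logger.warning("sample %s: %d missing gene values imputed to 0 (%s%s)",
                       sample_id, len(missing), ", ".join(missing[:5]),
                       ", ..." if len(missing) > 5 else "")
    X *= np.asarray(feature_mask, dtype=float)[None, :]
    return BioGraph(sample_id=sample_id, X_raw=X, feature_mask=tuple(feature_mask))


def gene_encoder(X_raw: np.ndarray,
                 weights: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
                 ) -> np.ndarray:
    """Two-layer perceptron applied independently to every gene row.

    ``weights = (W1, b1, W2, b2)`` with shapes (2,h), (h,), (h,l_b), (l_b,);
    ReLU between the layers, linear output.
    """
    W1, b1, W2, b2 = (np.asarray(w, dtype=float) for w in weights)
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.shape[1] != W1.shape[0] or W1.shape[1] != W2.shape[0]:
        raise ValueError(
            f"shape mismatch: X {X_raw.shape}, W1 {W1.shape}, W2 {W2.shape}")
    return np.maximum(X_raw @ W1 + b1, 0.0) @ W2 + b2
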