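"""Synthetic fixtures: molecules, PPI networks, omics, clinical tables, and
responses from a planted generative function.

The generator produces data in exactly the external formats the rest of the
package reads, so the full pipeline can be exercised with no downloads. The
planted response is a documented function of quantities both network
branches can represent — the drug's aromatic-atom fraction and the mean
expression / copy number of a designated correlated gene module — plus
Gaussian noise, which makes parameter-recovery experiments well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bio_graph import PPINetwork, build_ppi_adjacency
from .drug_graph import (AROMATIC_COL, DEGREE_SLICE, HCOUNT_SLICE,
                         HYBRID_SLICE, SYMBOL_SLICE, VALENCE_SLICE,
                         ATOM_VOCAB, N_ATOM_FEATURES, DrugGraph,
                         featurize_smiles, write_graph_text)
from .preprocess import ResponseRecord, transform_cnv, transform_expression

#: Small-molecule SMILES pool for the molecule generator (5–96 heavy atoms).
BUNDLED_SMILES: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "acetaminophen": "CC(=O)Nc1ccc(O)cc1",
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "pyridine": "c1ccncc1",
    "imidazole": "c1cnc[nH]1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "indole": "c1ccc2[nH]ccc2c1",
    "quinoline": "c1ccc2ncccc2c1",
    "nicotine": "CN1CCCC1c1cccnc1",
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "citrate": "OC(=O)CC(O)(C(=O)O)CC(=O)O",
    "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
    "dopamine": "NCCc1ccc(O)c(O)c1",
    "adenine": "Nc1ncnc2[nH]cnc12",
    "guanine": "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "cholesterol": "CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC21C",
    "penicillin_g": "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
    "gefitinib": "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",
    "imatinib": "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
    "erlotinib": "COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC",
    "sorafenib": "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1",
    "sunitinib": "CCN(CC)CCNC(=O)c1c(C)[nH]c(/C=C2\\C(=O)Nc3ccc(F)cc32)c1C",
    "camptothecin": "CCC1(O)C(=O)OCc2c1cc1n(c2=O)Cc2cc3ccccc3nc21",
    "tamoxifen": "CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "doxycycline": "CC1c2cccc(O)c2C(=O)C2=C(O)C3(O)C(=O)C(C(N)=O)=C(O)C(N(C)C)C3C(O)C12",
}

#: Planted-response coefficients: aromatic fraction, module-mean expression,
#: module-mean CNV, and the aromatic x expression interaction.
DEFAULT_PLANT_WEIGHTS = {"alpha": 2.0, "beta": 1.0, "gamma": 2.5, "delta": 0.5}

ATOM_RANGE = (5, 96)


@dataclass
class SyntheticConfig:
    """Study conditions for a generated dataset."""

    n_drugs: int = 20
    n_samples: int = 30
    n_genes: int = 50
    edge_model: str = "erdos_renyi"
    edge_density: float = 0.10
    attachment: int = 3
    noise_sd: float = 0.3
    weights: dict = field(default_factory=lambda: dict(DEFAULT_PLANT_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 5:
            raise ValueError("n_genes must be >= 5")
        if self.n_drugs < 2 or self.n_samples < 2:
            raise ValueError("n_drugs and n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_graph_molecule(drug_id: str, rng: np.random.Generator) -> DrugGraph:
    """A connected random graph with valid one-hot feature blocks.

    Degree one-hots mirror the realized adjacency degrees (capped at 10);
    the per-molecule aromatic probability is drawn uniformly so aromatic
    fractions vary across drugs.
    """
    n = int(rng.integers(ATOM_RANGE[0], ATOM_RANGE[1] + 1))
    A = np.zeros((n, n))
    for i in range(1, n):  # random spanning tree keeps the graph connected
        candidates = np.flatnonzero(A[:i].sum(axis=1)[:i] < 10) if i > 1 else [0]
        j = int(rng.choice(candidates)) if len(candidates) else int(rng.integers(i))
        A[i, j] = A[j, i] = 1
    n_extra = int(rng.binomial(n, 0.3))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j and A[i].sum() < 10 and A[j].sum() < 10:
            A[i, j] = A[j, i] = 1
    X = np.zeros((n, N_ATOM_FEATURES))
    symbols = rng.choice(len(ATOM_VOCAB) - 1, size=n,
                         p=_symbol_probs())
    p_arom = rng.uniform(0.0, 0.7)
    for i in range(n):
        X[i, SYMBOL_SLICE.start + symbols[i]] = 1
        X[i, DEGREE_SLICE.start + min(int(A[i].sum()), 10)] = 1
        X[i, VALENCE_SLICE.start + int(rng.integers(0, 5))] = 1
        X[i, HYBRID_SLICE.start + int(rng.integers(1, 3))] = 1  # SP2 or SP3
        X[i, AROMATIC_COL] = float(rng.random() < p_arom)
        X[i, HCOUNT_SLICE.start + int(rng.integers(0, 5))] = 1
    g = DrugGraph(drug_id=drug_id, X_raw=X, A_raw=A)
    g.validate()
    return g


def _symbol_probs() -> np.ndarray:
    p = np.full(len(ATOM_VOCAB) - 1, 0.2 / (len(ATOM_VOCAB) - 7))
    for k, w in zip((0, 1, 2, 3, 4, 7), (0.5, 0.12, 0.12, 0.02, 0.02, 0.02)):
        p[k] = w  # C, N, O, S, F, Cl dominate
    return p / p.sum()


def gen_molecules(n: int, seed: int = 0) -> list[DrugGraph]:
    """Generate ``n`` drug graphs: bundled SMILES mixed with random graphs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pool = list(BUNDLED_SMILES.items())
    out: list[DrugGraph] = []
    for i in range(n):
        drug_id = f"drug{i:03d}"
        if rng.random() < 0.5:
            name, smi = pool[int(rng.integers(len(pool)))]
            g = featurize_smiles(smi, drug_id=drug_id)
            g.smiles = smi  # type: ignore[attr-defined]
        else:
            g = _random_graph_molecule(drug_id, rng)
        out.append(g)
    return out


def gen_ppi_and_omics(cfg: SyntheticConfig
                      ) -> tuple[PPINetwork, pd.DataFrame, pd.DataFrame]:
    """Random PPI network plus per-gene expression and CNV matrices.

    Expression is log-normal TPM then log2(TPM+1); copy number is drawn
    around the neutral ratio 1 then log2(CN+1). The first ~10% of genes form
    a designated module sharing a per-sample latent factor in each omics
    channel — the correlated structure the planted response reads.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    module = module_genes(genes)

    if cfg.edge_model == "erdos_renyi":
        G = nx.gnp_random_graph(cfg.n_genes, cfg.edge_density,
                                seed=int(rng.integers(2**31)))
    elif cfg.edge_model == "preferential_attachment":
        G = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment,
                                     seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown edge_model '{cfg.edge_model}'")
    edges = [(genes[a], genes[b], 999.0) for a, b in G.edges()]
    network = build_ppi_adjacency(edges, genes, min_score=0.0)
    midx = [genes.index(g) for g in module]

    mu = rng.normal(1.5, 1.0, size=cfg.n_genes)
    u = rng.normal(0.0, 1.0, size=cfg.n_samples)  # shared expression factor
    v = rng.normal(0.0, 1.0, size=cfg.n_samples)  # shared CNV factor
    is_mod = np.isin(np.arange(cfg.n_genes), midx).astype(float)
    ln_tpm = (mu[:, None]
              + 0.8 * is_mod[:, None] * u[None, :]
              + rng.normal(0.0, 0.5, size=(cfg.n_genes, cfg.n_samples)))
    expr = pd.DataFrame(transform_expression(np.exp(ln_tpm)),
                        index=genes, columns=samples)
    ln_cn = (0.25 * is_mod[:, None] * v[None, :]
             + rng.normal(0.0, 0.15, size=(cfg.n_genes, cfg.n_samples)))
    cnv = pd.DataFrame(transform_cnv(np.exp(ln_cn)),
                       index=genes, columns=samples)
    return network, expr, cnv


def module_genes(genes: list[str]) -> list[str]:
    """The designated correlated module: the first max(2, 10%) genes."""
    return genes[:max(2, len(genes) // 10)]


def aromatic_fraction(drug: DrugGraph) -> float:
    return float(drug.X_raw[:, AROMATIC_COL].mean())


def plant_response(drug: DrugGraph, expr_col: pd.Series, cnv_col: pd.Series,
                   module: list[str], weights: dict | None = None,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> float:
    """Planted ln IC50 for one drug–sample pair.

    ln IC50 = alpha * aromatic fraction + beta * mean module expression
            + gamma * mean module CNV + delta * (aromatic x expression)
            + N(0, noise_sd)
    """
    w = dict(DEFAULT_PLANT_WEIGHTS, **(weights or {}))
    arom = aromatic_fraction(drug)
    me = float(expr_col.loc[module].mean())
    mc = float(cnv_col.loc[module].mean())
    y = (w["alpha"] * arom + w["beta"] * me + w["gamma"] * mc
         + w["delta"] * arom * me)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        y += float(rng.normal(0.0, noise_sd))
    return y


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    drugs: list[DrugGraph]
    network: PPINetwork
    expr: pd.DataFrame
    cnv: pd.DataFrame
    responses: list[ResponseRecord]
    cancer_types: dict[str, str]


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """All-pairs synthetic dataset under the planted response function."""
    drugs = gen_molecules(cfg.n_drugs, seed=cfg.seed)
    network, expr, cnv = gen_ppi_and_omics(cfg)
    module = module_genes(network.genes)
    rng = np.random.default_rng(cfg.seed + 2)
    responses = [
        ResponseRecord(d.drug_id, s,
                       plant_response(d, expr[s], cnv[s], module, cfg.weights,
                                      cfg.noise_sd, rng))
        for d in drugs for s in expr.columns
    ]
    # cancer types in blocks of >= 10 samples
    n_types = max(1, cfg.n_samples // 15)
    cancer_types = {s: f"TYPE{j % n_types}" for j, s in enumerate(expr.columns)}
    return SyntheticDataset(config=cfg, drugs=drugs, network=network,
                            expr=expr, cnv=cnv, responses=responses,
                            cancer_types=cancer_types)


def write_fixtures(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Emit the dataset in the external formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(ds.config.seed + 3)

    with open(out / "smiles.tsv", "w") as fh:
        fh.write("id\tsmiles\n")
        for d in ds.drugs:
            if hasattr(d, "smiles"):
                fh.write(f"{d.drug_id}\t{d.smiles}\n")
    (out / "drugs").mkdir(exist_ok=True)
    for d in ds.drugs:
        write_graph_text(d, out / "drugs" / f"{d.drug_id}.txt")

    ds.expr.to_csv(out / "expr.tsv", sep="\t", index_label="gene")
    ds.cnv.to_csv(out / "cnv.tsv", sep="\t", index_label="gene")
    (out / "genes.txt").write_text("\n".join(ds.network.genes) + "\n")
    with open(out / "ppi.tsv", "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        ii, jj = np.nonzero(np.triu(ds.network.A_b))
        for i, j in zip(ii, jj):
            fh.write(f"{ds.network.genes[i]}\t{ds.network.genes[j]}\t999\n")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tcancer_type\texpr_available\tcnv_available\n")
        for s in ds.expr.columns:
            fh.write(f"{s}\t{ds.cancer_types[s]}\tTrue\tTrue\n")
    with open(out / "responses.tsv", "w") as fh:
        fh.write("drug_id\tsample_id\tln_ic50\n")
        for r in ds.responses:
            fh.write(f"{r.drug_id}\t{r.sample_id}\t{r.ln_ic50:.6f}\n")

    # clinical-mode fixtures: gene intervals, segment CNV, annotations, MSC
    with open(out / "gene_intervals.tsv", "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        pos = 1
        for g in ds.network.genes:
            length = int(rng.integers(1000, 5000))
            fh.write(f"{g}\tchr1\t{pos}\t{pos + length - 1}\n")
            pos += length + int(rng.integers(100, 1000))
    with open(out / "segments.tsv", "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tratio\n")
        for s in ds.expr.columns:
            pos = 1
            while pos < 200_000:
                length = int(rng.integers(2000, 20000))
                ratio = float(np.exp(rng.normal(0.0, 0.2)))
                fh.write(f"{s}\tchr1\t{pos}\t{pos + length - 1}\t{ratio:.4f}\n")
                pos += length
    per_drug = {d.drug_id: np.median([r.ln_ic50 for r in ds.responses
                                      if r.drug_id == d.drug_id])
                for d in ds.drugs}
    with open(out / "msc.tsv", "w") as fh:
        fh.write("drug\tmsc_uM\n")
        for d, med in per_drug.items():
            fh.write(f"{d}\t{np.exp(med):.6f}\n")
    cats = ("complete response", "partial response",
            "clinical progressive disease", "stable disease")
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("sample\tdrug\tcategory\n")
        for s in ds.expr.columns:
            for d in rng.choice([dd.drug_id for dd in ds.drugs], size=3,
                                replace=False):
                fh.write(f"{s}\t{d}\t{cats[int(rng.integers(4))]}\n")
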