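"""The dual graph-convolutional response model.

Two GCN branches — one over the drug's padded molecular graph, one over the
shared cancer-gene PPI graph whose node features pass through a two-layer
gene encoder first — are pooled by masked global max pooling, concatenated,
and fed to an MLP head that regresses the natural-log IC50 (µM).

Each GCN block applies: propagate (A_hat H W) -> masked batch-norm -> ReLU
-> dropout, and zeroes padded rows. Training minimizes mean squared error
with Adam; an internal seeded 90/10 split drives early stopping on
validation loss. One seed controls weight initialization, the split,
shuffling and dropout, so repeated runs on one machine are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .bio_graph import BioGraph, PPINetwork
from .drug_graph import PaddedDrugGraph, N_ATOM_FEATURES
from .gcn_core import normalize_adjacency
from .preprocess import ResponseRecord, ZScoreNormalizer

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "dualgcn-checkpoint-v1"


class FingerprintError(ValueError):
    """The bio-graph gene order does not match the model's."""


def gene_fingerprint(genes: list[str]) -> str:
    return hashlib.sha256("\n".join(genes).encode()).hexdigest()[:16]


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Widths default to CPU-scale values (two 64-wide layers per branch); the
    deeper/wider settings used on GPU corpora are reachable through the same
    fields.
    """

    drug_gcn_widths: list[int] = field(default_factory=lambda: [64, 64])
    bio_gcn_widths: list[int] = field(default_factory=lambda: [64, 64])
    gene_encoder_dims: tuple[int, int] = (32, 32)  # (hidden, l_b)
    head_widths: list[int] = field(default_factory=lambda: [128, 64, 1])
    dropout_rate: float = 0.2
    use_batchnorm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    feature_mask: tuple[int, int] = (1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        widths = [*self.drug_gcn_widths, *self.bio_gcn_widths,
                  *self.head_widths, *self.gene_encoder_dims]
        if any(w < 1 for w in widths):
            raise ValueError("all layer widths must be >= 1")
        if self.head_widths[-1] != 1:
            raise ValueError("head must end in a scalar output")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["gene_encoder_dims"] = tuple(d["gene_encoder_dims"])
        d["feature_mask"] = tuple(d["feature_mask"])
        return cls(**d)


class _GCNBlock:
    """propagate -> (masked batch-norm) -> ReLU -> dropout -> re-mask."""

    def __init__(self, in_dim: int, out_dim: int, dropout: float,
                 use_bn: bool, rng: np.random.Generator, name: str) -> None:
        self.dense = nn.Dense(in_dim, out_dim, rng, bias=not use_bn, name=name)
        self.bn = nn.MaskedBatchNorm(out_dim, name=f"{name}.bn") if use_bn else None
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(dropout)
        self._A: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        return self.dense.params() + (self.bn.params() if self.bn else [])

    def forward(self, H: np.ndarray, A_hat: np.ndarray, mask: np.ndarray,
                training: bool, rng: np.random.Generator | None) -> np.ndarray:
        self._A, self._mask = A_hat, mask
        Z = self.dense.forward(A_hat @ H)
        if self.bn is not None:
            Z = self.bn.forward(Z, mask, training)
        Z = self.relu.forward(Z)
        Z = self.dropout.forward(Z, training, rng)
        return Z * mask[..., None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = gy * self._mask[..., None]
        gy = self.dropout.backward(gy)
        gy = self.relu.backward(gy)
        if self.bn is not None:
            gy = self.bn.backward(gy)
        gP = self.dense.backward(gy)
        # A_hat is symmetric, so A^T g == A g
        return self._A @ gP


class DualGCN:
    """The assembled dual-branch network bound to one PPI gene order."""

    def __init__(self, config: ModelConfig, network: PPINetwork,
                 normalizer: ZScoreNormalizer | None = None) -> None:
        self.config = config
        self.network = network
        self.normalizer = normalizer
        self.fingerprint = gene_fingerprint(network.genes)
        self.history: list[dict] = []
        self.y_offset = 0.0  # training-set target mean, added back at inference
        self._A_bio = normalize_adjacency(network.A_b).A_hat.astype(nn.DTYPE)
        self._rng = np.random.default_rng(config.seed)
        self._build(self._rng)

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self.drug_blocks: list[_GCNBlock] = []
        d = N_ATOM_FEATURES
        for i, w in enumerate(cfg.drug_gcn_widths):
            self.drug_blocks.append(_GCNBlock(d, w, cfg.dropout_rate,
                                              cfg.use_batchnorm, rng, f"drug{i}"))
            d = w
        h, l_b = cfg.gene_encoder_dims
        self.enc1 = nn.Dense(2, h, rng, name="enc1")
        self.enc_relu = nn.ReLU()
        self.enc2 = nn.Dense(h, l_b, rng, name="enc2")
        self.bio_blocks: list[_GCNBlock] = []
        d = l_b
        for i, w in enumerate(cfg.bio_gcn_widths):
            self.bio_blocks.append(_GCNBlock(d, w, cfg.dropout_rate,
                                             cfg.use_batchnorm, rng, f"bio{i}"))
            d = w
        self.drug_pool = nn.MaskedMaxPool()
        self.bio_pool = nn.MaskedMaxPool()
        d = cfg.drug_gcn_widths[-1] + cfg.bio_gcn_widths[-1]
        self.head: list = []
        for i, w in enumerate(cfg.head_widths[:-1]):
            self.head.append(("dense", nn.Dense(d, w, rng, name=f"head{i}")))
            self.head.append(("relu", nn.ReLU()))
            self.head.append(("dropout", nn.Dropout(cfg.dropout_rate)))
            d = w
        self.head.append(("dense", nn.Dense(d, 1, rng, name="head_out")))

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for blk in self.drug_blocks:
            out += blk.params()
        out += self.enc1.params() + self.enc2.params()
        for blk in self.bio_blocks:
            out += blk.params()
        for kind, layer in self.head:
            if kind == "dense":
                out += layer.params()
        return out

    # ------------------------------------------------------------ forward

    def drug_embedding(self, X: np.ndarray, A_hat: np.ndarray,
                       mask: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Pooled drug-branch embedding; accepts native or padded graphs."""
        H = np.asarray(X, dtype=nn.DTYPE)
        for blk in self.drug_blocks:
            H = blk.forward(H, A_hat.astype(nn.DTYPE), mask.astype(nn.DTYPE),
                            training, rng)
        return self.drug_pool.forward(H, mask)

    def _forward_batch(self, Xd, Ad, md, Xb, training: bool,
                       rng: np.random.Generator | None) -> np.ndarray:
        H = Xd
        for blk in self.drug_blocks:
            H = blk.forward(H, Ad, md, training, rng)
        zd = self.drug_pool.forward(H, md)

        G = self.enc2.forward(self.enc_relu.forward(self.enc1.forward(Xb)))
        mb = np.ones(G.shape[:-1], dtype=nn.DTYPE)
        for blk in self.bio_blocks:
            G = blk.forward(G, self._A_bio, mb, training, rng)
        zb = self.bio_pool.forward(G, mb)

        z = np.concatenate([zd, zb], axis=-1)
        self._split = zd.shape[-1]
        for kind, layer in self.head:
            if kind == "dropout":
                z = layer.forward(z, training, rng)
            else:
                z = layer.forward(z)
        return z[..., 0]

    def _backward_batch(self, gy: np.ndarray) -> None:
        g = gy[..., None].astype(nn.DTYPE)
        for kind, layer in reversed(self.head):
            g = layer.backward(g)
        gd, gb = g[..., :self._split], g[..., self._split:]
        g = self.bio_pool.backward(gb)
        for blk in reversed(self.bio_blocks):
            g = blk.backward(g)
        g = self.enc1.backward(self.enc_relu.backward(self.enc2.backward(g)))
        g = self.drug_pool.backward(gd)
        for blk in reversed(self.drug_blocks):
            g = blk.backward(g)

    def forward_pair(self, drug: PaddedDrugGraph, bio: BioGraph,
                     training: bool = False) -> float:
        """Predict ln IC50 (µM) for one drug–sample pair."""
        if bio.X_raw.shape[0] != self.network.n_genes:
            raise FingerprintError(
                f"bio graph has {bio.X_raw.shape[0]} genes; model expects "
                f"{self.network.n_genes} (fingerprint {self.fingerprint})")
        Ad = normalize_adjacency(drug.A).A_hat
        Xb = bio.X_raw * np.asarray(self.config.feature_mask, float)[None, :]
        y = self._forward_batch(
            drug.X[None].astype(nn.DTYPE), Ad[None].astype(nn.DTYPE),
            drug.node_mask[None].astype(nn.DTYPE), Xb[None].astype(nn.DTYPE),
            training=training, rng=self._rng if training else None)
        return float(y[0]) + self.y_offset

    # ------------------------------------------------------------ training

    def fit(self, drugs: dict[str, PaddedDrugGraph], bios: dict[str, BioGraph],
            responses: list[ResponseRecord]) -> "DualGCN":
        """Train by MSE on ln IC50 with Adam and early stopping."""
        cfg = self.config
        if len(responses) < 2 * cfg.batch_size:
            raise ValueError(
                f"dataset has {len(responses)} pairs; need >= 2*batch_size "
                f"({2 * cfg.batch_size})")
        drug_ids = sorted(drugs)
        samp_ids = sorted(bios)
        dmap = {d: i for i, d in enumerate(drug_ids)}
        smap = {s: i for i, s in enumerate(samp_ids)}
        fmask = np.asarray(cfg.feature_mask, dtype=nn.DTYPE)
        Xd = np.stack([drugs[d].X for d in drug_ids]).astype(nn.DTYPE)
        Ad = np.stack([normalize_adjacency(drugs[d].A).A_hat
                       for d in drug_ids]).astype(nn.DTYPE)
        md = np.stack([drugs[d].node_mask for d in drug_ids]).astype(nn.DTYPE)
        Xb = np.stack([bios[s].X_raw for s in samp_ids]).astype(nn.DTYPE) * fmask
        di = np.array([dmap[r.drug_id] for r in responses])
        si = np.array([smap[r.sample_id] for r in responses])
        y = np.array([r.ln_ic50 for r in responses], dtype=nn.DTYPE)

        rng = self._rng
        n = len(responses)
        order = rng.permutation(n)
        n_val = int(round(n * cfg.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        # regress on centered targets; the offset is restored at inference
        self.y_offset = float(np.mean(y[tr_idx]))
        y = y - nn.DTYPE(self.y_offset)
        opt = nn.Adam(self.params(), lr=cfg.learning_rate)
        best_val, best_state, wait = np.inf, None, 0
        self.history = []
        for epoch in range(cfg.max_epochs):
            perm = tr_idx[rng.permutation(len(tr_idx))]
            losses = []
            for start in range(0, len(perm), cfg.batch_size):
                b = perm[start:start + cfg.batch_size]
                opt.zero_grad()
                pred = self._forward_batch(Xd[di[b]], Ad[di[b]], md[di[b]],
                                           Xb[si[b]], training=True, rng=rng)
                err = pred - y[b]
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate")
                self._backward_batch((2.0 / len(b)) * err)
                opt.step()
                losses.append(loss)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if n_val > 0:
                vp = self._forward_batch(Xd[di[val_idx]], Ad[di[val_idx]],
                                         md[di[val_idx]], Xb[si[val_idx]],
                                         training=False, rng=None)
                entry["val_loss"] = float(np.mean((vp - y[val_idx]) ** 2))
                if entry["val_loss"] < best_val - 1e-7:
                    best_val, wait = entry["val_loss"], 0
                    best_state = self._state_arrays()
                else:
                    wait += 1
            self.history.append(entry)
            if n_val > 0 and wait >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
        if best_state is not None:
            self._load_state_arrays(best_state)
        return self

    # --------------------------------------------------------- persistence

    def _state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for j, bn in enumerate(self._batchnorms()):
            state[f"bn_{j}_mean"] = bn.running_mean.copy()
            state[f"bn_{j}_var"] = bn.running_var.copy()
        return state

    def _load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"param_{i}"].astype(nn.DTYPE).copy()
            p.grad = np.zeros_like(p.value)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = state[f"bn_{j}_mean"].astype(nn.DTYPE).copy()
            bn.running_var = state[f"bn_{j}_var"].astype(nn.DTYPE).copy()

    def _batchnorms(self) -> list[nn.MaskedBatchNorm]:
        return [blk.bn for blk in (*self.drug_blocks, *self.bio_blocks)
                if blk.bn is not None]

    def save(self, path: str | Path) -> None:
        """Write a single-file checkpoint (weights + config + normalizer)."""
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": self.config.to_dict(),
            "genes": self.network.genes,
            "fingerprint": self.fingerprint,
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "history": self.history,
            "y_offset": self.y_offset,
        }
        arrays = self._state_arrays()
        arrays["ppi_adjacency"] = self.network.A_b.astype(np.int8)
        with open(path, "wb") as fh:  # file handle keeps the exact path
            np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DualGCN":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"].tobytes()).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"{path}: not a {CHECKPOINT_FORMAT} file")
            network = PPINetwork(genes=list(meta["genes"]),
                                 A_b=npz["ppi_adjacency"].astype(np.int8))
            model = cls(ModelConfig.from_dict(meta["config"]), network,
                        normalizer=(ZScoreNormalizer.from_dict(meta["normalizer"])
                                    if meta["normalizer"] else None))
            model.history = meta["history"]
            model.y_offset = float(meta.get("y_offset", 0.0))
            model._load_state_arrays({k: npz[k] for k in npz.files if k != "meta"})
        return model


def forward(drug: PaddedDrugGraph, bio: BioGraph, network: PPINetwork,
            model: DualGCN, training: bool = False) -> float:
    """Predict ln IC50 for one pair, checking the gene-order fingerprint."""
    if gene_fingerprint(network.genes) != model.fingerprint:
        raise FingerprintError("network gene order differs from the model's")
    return model.forward_pair(drug, bio, training=training)


def train(dataset: list[tuple[PaddedDrugGraph, BioGraph, ResponseRecord]],
          network: PPINetwork, config: ModelConfig,
          normalizer: ZScoreNormalizer | None = None) -> DualGCN:
    """Train a :class:`DualGCN` on (drug graph, bio graph, response) triples."""
    if not dataset:
        raise ValueError("dataset is empty")
    drugs = {d.drug_id: d for d, _, _ in dataset}
    bios = {b.sample_id: b for _, b, _ in dataset}
    responses = [r for _, _, r in dataset]
    return DualGCN(config, network, normalizer=normalizer).fit(drugs, bios, responses)


def predict_batch(pairs: list[tuple[str, str]], model: DualGCN,
                  drug_store: dict[str, PaddedDrugGraph],
                  bio_store: dict[str, BioGraph]) -> list[float]:
    """Inference for (drug_id, sample_id) pairs; output order matches input."""
    for d, s in pairs:
        if d not in drug_store:
            raise KeyError(f"unknown drug id '{d}'")
        if s not in bio_store:
            raise KeyError(f"unknown sample id '{s}'")
    if not pairs:
        return []
    fmask = np.asarray(model.config.feature_mask, dtype=nn.DTYPE)
    a_cache = {d: normalize_adjacency(g.A).A_hat.astype(nn.DTYPE)
               for d, g in drug_store.items()}
    out: list[float] = []
    for start in range(0, len(pairs), 256):
        chunk = pairs[start:start + 256]
        Xd = np.stack([drug_store[d].X for d, _ in chunk]).astype(nn.DTYPE)
        Ad = np.stack([a_cache[d] for d, _ in chunk])
        md = np.stack([drug_store[d].node_mask for d, _ in chunk]).astype(nn.DTYPE)
        Xb = np.stack([bio_store[s].X_raw for _, s in chunk]).astype(nn.DTYPE) * fmask
        pred = model._forward_batch(Xd, Ad, md, Xb, training=False, rng=None)
        out.extend(float(v) + model.y_offset for v in pred)
    return out
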