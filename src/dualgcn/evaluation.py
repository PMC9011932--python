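"""Cross-validation harness and regression metrics.

Evaluation follows the protocol used for drug-response regressors: k-fold
cross-validation over drug–sample pairs with Pearson and Spearman
correlation and RMSE, reported overall and aggregated per group (cancer
type or drug) as the across-fold mean and variance of the within-fold
Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroupStats:
    """Across-fold summary of within-fold Pearson correlations for one group."""

    mean_r: float
    var_r: float
    mean_n: float
    n_folds: int


@dataclass
class EvalReport:
    overall: dict[str, float]
    per_fold: list[dict[str, float]]
    per_group: dict[str, GroupStats] = field(default_factory=dict)
    fold_assignments: dict[tuple, int] = field(default_factory=dict)


def kfold_split(pairs: list, k: int = 5, seed: int = 0) -> list[list]:
    """Seeded random partition into k folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(pairs) < k:
        raise ValueError(f"cannot split {len(pairs)} pairs into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [[pairs[i] for i in chunk] for chunk in np.array_split(order, k)]


def regression_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(Pearson r, Spearman rho, RMSE).

    Spearman uses average ranks for ties. If either vector has zero
    variance the correlations are undefined and returned as NaN with a
    warning, never silently as 0.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 2:
        raise ValueError("metrics need at least 2 observations")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant input: correlation undefined (NaN)")
        return float("nan"), float("nan"), rmse
    pearson = float(stats.pearsonr(y_true, y_pred).statistic)
    spearman = float(stats.spearmanr(y_true, y_pred).statistic)
    return pearson, spearman, rmse


def per_group_report(records: list[tuple[str, int, float, float]]
                     ) -> dict[str, GroupStats]:
    """Aggregate within-fold Pearson correlations per group.

    ``records`` holds (group_id, fold, y_true, y_pred) per pair. For each
    group and fold with >= 2 pairs and non-constant vectors, the fold's
    Pearson r is computed; groups are summarized by the mean and population
    variance of r across their scored folds plus the mean per-fold pair
    count, and returned sorted by mean r descending. Groups scoreable in no
    fold are excluded with a warning.
    """
    by_gf: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for gid, fold, yt, yp in records:
        by_gf.setdefault((gid, fold), []).append((yt, yp))
    per_group_r: dict[str, list[float]] = {}
    per_group_n: dict[str, list[int]] = {}
    for (gid, fold), vals in sorted(by_gf.items()):
        yt = np.array([v[0] for v in vals])
        yp = np.array([v[1] for v in vals])
        if len(vals) < 2 or np.ptp(yt) == 0 or np.ptp(yp) == 0:
            logger.info("group %s fold %d skipped (degenerate)", gid, fold)
            continue
        r = float(stats.pearsonr(yt, yp).statistic)
        per_group_r.setdefault(gid, []).append(r)
        per_group_n.setdefault(gid, []).append(len(vals))
    all_groups = {gid for gid, _, _, _ in records}
    for gid in all_groups - per_group_r.keys():
        logger.warning("group %s scoreable in no fold; excluded", gid)
    out = {gid: GroupStats(mean_r=float(np.mean(rs)),
                           var_r=float(np.var(rs)),
                           mean_n=float(np.mean(per_group_n[gid])),
                           n_folds=len(rs))
           for gid, rs in per_group_r.items()}
    return dict(sorted(out.items(), key=lambda kv: -kv[1].mean_r))


def cross_validate(dataset, network, config, k: int = 5, seed: int = 0,
                   groups: dict[tuple[str, str], str] | None = None,
                   raw_expr=None, raw_cnv=None) -> EvalReport:
    """k-fold CV of the dual-GCN over drug–sample pairs.

    ``dataset`` is a list of (PaddedDrugGraph, BioGraph, ResponseRecord)
    triples carrying *unnormalized* (log-transformed) omics when
    ``raw_expr``/``raw_cnv`` DataFrames are given: per fold, a z-score
    normalizer is fit on the training folds' samples only and applied to
    both sides, so no validation statistics leak into training.
    ``groups`` optionally maps (drug_id, sample_id) to a group label for the
    per-group aggregation.
    """
    from .bio_graph import BioGraph, assemble_bio_graph
    from .model import DualGCN
    from .preprocess import ZScoreNormalizer

    pair_keys = [(d.drug_id, b.sample_id) for d, b, _ in dataset]
    folds = kfold_split(list(range(len(dataset))), k=k, seed=seed)
    fold_assignments = {pair_keys[i]: f for f, idxs in enumerate(folds)
                        for i in idxs}
    drugs = {d.drug_id: d for d, _, _ in dataset}
    per_fold, records = [], []
    for f, test_idx in enumerate(folds):
        train_idx = [i for ff, idxs in enumerate(folds) if ff != f for i in idxs]
        train_samples = sorted({dataset[i][1].sample_id for i in train_idx})
        if raw_expr is not None:
            norm_e = ZScoreNormalizer().fit(raw_expr[train_samples])
            norm_c = ZScoreNormalizer().fit(raw_cnv[train_samples])
            expr_z, cnv_z = norm_e.transform(raw_expr), norm_c.transform(raw_cnv)
            bios = {s: assemble_bio_graph(expr_z[s].to_dict(), cnv_z[s].to_dict(),
                                          network, config.feature_mask, sample_id=s)
                    for s in raw_expr.columns}
        else:
            bios = {b.sample_id: b for _, b, _ in dataset}
        model = DualGCN(config, network).fit(
            drugs, {s: bios[s] for s in train_samples},
            [dataset[i][2] for i in train_idx])
        from .model import predict_batch
        test_pairs = [pair_keys[i] for i in test_idx]
        preds = predict_batch(test_pairs, model, drugs, bios)
        y_true = [dataset[i][2].ln_ic50 for i in test_idx]
        pr, sp, rmse = regression_metrics(y_true, preds)
        per_fold.append({"pearson": pr, "spearman": sp, "rmse": rmse})
        for (dk, sk), yt, yp in zip(test_pairs, y_true, preds):
            gid = groups.get((dk, sk)) if groups else "all"
            records.append((gid, f, yt, yp))
    overall = {m: float(np.mean([pf[m] for pf in per_fold]))
               for m in ("pearson", "spearman", "rmse")}
    overall.update({f"{m}_sd": float(np.std([pf[m] for pf in per_fold]))
                    for m in ("pearson", "spearman", "rmse")})
    return EvalReport(overall=overall, per_fold=per_fold,
                      per_group=per_group_report(records),
                      fold_assignments=fold_assignments)
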