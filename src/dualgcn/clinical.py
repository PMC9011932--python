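"""Clinical case-study machinery: response binarization, the drug
sensitivity score (DSS), and ROC/AUC concordance.

Clinical response annotations are qualitative grades, while model output is
a quantitative ln IC50; the DSS puts predictions on a scale comparable
across drugs by measuring the signed log-distance of the (linear, µM) IC50
from the drug's max screening concentration (MSC):

    DSS = (-1)^{I(IC50 > MSC)} * ln(|IC50 - MSC| / MSC + 1)

Positive DSS (IC50 below MSC) indicates predicted sensitivity; the score is
bounded above by ln 2 and unbounded below.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

SENSITIVE, RESISTANT = "sensitive", "resistant"

#: TCGA response grades and their binarization.
_CATEGORY_MAP = {
    "complete response": SENSITIVE,
    "partial response": SENSITIVE,
    "clinical progressive disease": RESISTANT,
    "stable disease": RESISTANT,
}


@dataclass
class DSSRecord:
    sample_id: str
    drug_id: str
    ic50: float  # linear µM
    msc: float
    dss: float
    label: str | None = None


def binarize_response(annotation: str) -> str:
    """Map a TCGA response grade to 'sensitive' or 'resistant'."""
    key = annotation.strip().lower()
    if key not in _CATEGORY_MAP:
        raise ValueError(
            f"unrecognized response category '{annotation}'; expected one of "
            f"{sorted(_CATEGORY_MAP)}")
    return _CATEGORY_MAP[key]


def dss(ic50: float, msc: float) -> float:
    """Drug sensitivity score of a linear-scale IC50 (µM) against the MSC.

    Callers holding a model prediction must exponentiate it first (the model
    emits natural-log µM).
    """
    if not (msc > 0 and math.isfinite(msc)):
        raise ValueError("MSC denotes max screening concentration; must be > 0")
    if not (ic50 > 0 and math.isfinite(ic50)):
        raise ValueError("IC50 must be positive and finite")
    sign = -1.0 if ic50 > msc else 1.0
    return sign * math.log(abs(ic50 - msc) / msc + 1.0)


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """ROC using the observed scores as discrimination thresholds.

    Positive class = sensitive. Returns the Mann–Whitney AUC (ties credit
    0.5) and the (FPR, TPR) curve points, one per distinct threshold plus
    the (0,0) sentinel; trapezoidal integration of the curve equals the
    returned AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == SENSITIVE else 0 if l == RESISTANT else l
                    for l in labels], dtype=float)
    if len(scores) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # process tied scores together
            j += 1
        tp += int(yy[i:j].sum())
        fp += (j - i) - int(yy[i:j].sum())
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    # Mann–Whitney with 0.5 credit for ties, via rank sums (average ranks)
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc), curve


def compute_dss_records(predictions: dict[tuple[str, str], float],
                        msc: dict[str, float],
                        annotations: list[tuple[str, str, str]] | None = None
                        ) -> list[DSSRecord]:
    """Build DSS records from ln-IC50 predictions and per-drug MSC values.

    ``predictions`` maps (sample_id, drug_id) to the model's natural-log µM
    output. When a patient has multiple annotation records for one drug the
    worst response wins (resistant dominates), with a log message.
    """
    labels: dict[tuple[str, str], str] = {}
    for sample, drug, category in annotations or []:
        lab = binarize_response(category)
        key = (sample, drug)
        if key in labels and labels[key] != lab:
            logger.info("conflicting annotations for %s; resistant wins", key)
            lab = RESISTANT
        labels[key] = lab
    out = []
    for (sample, drug), ln_ic50 in predictions.items():
        if drug not in msc:
            raise KeyError(f"no max screening concentration for drug '{drug}'")
        ic50 = math.exp(ln_ic50)
        out.append(DSSRecord(sample_id=sample, drug_id=drug, ic50=ic50,
                             msc=msc[drug], dss=dss(ic50, msc[drug]),
                             label=labels.get((sample, drug))))
    return out
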