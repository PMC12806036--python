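"""Multi-label evaluation: precision, coverage, accuracy, absolute true/false.

For sample i with true label set y_i and predicted set ybar_i over M
classes (N samples):

* precision      = mean |y ∩ ybar| / |ybar|   (an empty prediction scores 0)
* coverage       = mean |y ∩ ybar| / |y|
* accuracy       = mean |y ∩ ybar| / |y ∪ ybar|  (per-sample Jaccard)
* absolute true  = fraction of samples with ybar identical to y
* absolute false = mean (|y ∪ ybar| − |y ∩ ybar|) / M  (Hamming-style)

The chain absolute_true <= accuracy <= min(precision, coverage) holds per
sample and hence for the means.  Thresholding can produce empty predicted
sets; the precision term is then defined as 0, penalizing abstention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["MetricsReport", "multilabel_metrics", "report_to_json", "report_from_json"]


@dataclass
class MetricsReport:
    precision: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    n_samples: int
    n_labels: int

    def as_dict(self) -> dict:
        return asdict(self)


def multilabel_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Compute the five multi-label metrics from binary N x M matrices."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 2:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, m in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1")
    n, m_labels = y_true.shape
    if n == 0:
        raise ValueError("need at least one sample")
    true_sz = y_true.sum(axis=1)
    if (true_sz == 0).any():
        raise ValueError("every true label set must be nonempty (coverage undefined)")
    inter = np.logical_and(y_true, y_pred).sum(axis=1).astype(float)
    union = np.logical_or(y_true, y_pred).sum(axis=1).astype(float)
    pred_sz = y_pred.sum(axis=1).astype(float)
    precision = float(np.mean(np.divide(inter, pred_sz, out=np.zeros(n), where=pred_sz > 0)))
    coverage = float(np.mean(inter / true_sz))
    accuracy = float(np.mean(inter / union))
    absolute_true = float(np.mean((y_true == y_pred).all(axis=1)))
    absolute_false = float(np.mean((union - inter) / m_labels))
    return MetricsReport(
        precision=precision,
        coverage=coverage,
        accuracy=accuracy,
        absolute_true=absolute_true,
        absolute_false=absolute_false,
        n_samples=int(n),
        n_labels=int(m_labels),
    )


def report_to_json(report: MetricsReport) -> str:
    """Serialize with >= 6 significant digits per numeric field."""
    d = report.as_dict()
    out = {
        k: (float(f"{v:.10g}") if isinstance(v, float) else v) for k, v in d.items()
    }
    return json.dumps(out, indent=2)


def report_from_json(text: str) -> MetricsReport:
    data = json.loads(text)
    required = {
        "precision", "coverage", "accuracy", "absolute_true", "absolute_false",
        "n_samples", "n_labels",
    }
    missing = required - set(data)
    if missing:
        raise ValueError(f"metrics report missing keys: {sorted(missing)}")
    return MetricsReport(**{k: data[k] for k in required})
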