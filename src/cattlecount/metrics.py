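"""Count-based evaluation metrics at object, image and survey level.

Metrics are tallied from (estimate, truth) count pairs, not from spatial
detection matching: per pair TP = min(Ce, Ct), FP = max(0, Ce − Ct),
FN = max(0, Ct − Ce). This makes precision equal recall whenever the
summed estimates equal the summed truths — the balance property a
well-tuned counter should show. The "standard deviation of the error"
reported alongside is the mean absolute deviation, implemented exactly
as printed and named ``mean_abs_deviation`` here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class MetricsReport:
    precision: float                  # percent
    recall: float                     # percent
    f1: float                         # percent
    mean_deviation: float
    mean_abs_deviation: float
    min_deviation: float              # most negative deviation
    max_deviation: float              # most positive deviation
    n: int
    by_stratum: dict[str, "MetricsReport"] = field(default_factory=dict)
    confusion: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall,
             "f1": self.f1, "mean_deviation": self.mean_deviation,
             "mean_abs_deviation": self.mean_abs_deviation,
             "min_deviation": self.min_deviation,
             "max_deviation": self.max_deviation, "n": self.n}
        if self.by_stratum:
            d["by_stratum"] = {k: v.to_dict()
                               for k, v in self.by_stratum.items()}
        return d


def count_metrics(pairs: Sequence[tuple[int, int]],
                  strata: Optional[Sequence] = None) -> MetricsReport:
    """Precision/recall/F1 and deviation statistics over count pairs.

    ``pairs`` holds (estimate, truth) counts; ``strata`` are optional
    labels (e.g. cluster size or structure type) for per-stratum
    sub-reports and the confusion matrix.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (estimate, truth) pair")
    if strata is not None and len(strata) != len(pairs):
        raise ValueError("strata must align with pairs")

    est = np.array([p[0] for p in pairs], dtype=float)
    tru = np.array([p[1] for p in pairs], dtype=float)
    tp = np.minimum(est, tru).sum()
    fp = np.maximum(0.0, est - tru).sum()
    fn = np.maximum(0.0, tru - est).sum()
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    dev = est - tru

    report = MetricsReport(
        precision=precision, recall=recall, f1=f1,
        mean_deviation=float(dev.mean()),
        mean_abs_deviation=float(np.abs(dev).mean()),
        min_deviation=float(dev.min()),
        max_deviation=float(dev.max()),
        n=len(pairs),
    )
    if strata is not None:
        labels = np.asarray(strata)
        for lab in pd.unique(labels):
            sel = labels == lab
            sub = [pairs[i] for i in np.nonzero(sel)[0]]
            report.by_stratum[str(lab)] = count_metrics(sub)
        report.confusion = confusion_matrix(pairs)
    return report


def confusion_matrix(pairs: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """Actual × estimated count cross-tabulation (absolute frequencies)."""
    est = [p[0] for p in pairs]
    tru = [p[1] for p in pairs]
    return pd.crosstab(pd.Series(tru, name="actual"),
                       pd.Series(est, name="estimated"))
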