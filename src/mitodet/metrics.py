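"""Confusion counts and the 11-metric evaluation suite.

The suite reports sensitivity, specificity, accuracy, F-measure, critical
success index (CSI), balanced accuracy (BA), Fowlkes-Mallows index (FMI),
markedness (MK = precision + NPV - 1), negative likelihood ratio
(NLR = (1 - Sen)/Spec), and the false positive / negative rates, all
derived from a single 2x2 tally. Zero denominators yield a sentinel value
of 0 together with a ``degenerate`` flag so reports stay serializable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_labels",
    "metric_suite",
    "METRIC_COLUMNS",
]

#: Column order used by the multi-run comparison writer.
METRIC_COLUMNS = [
    "sen", "spec", "acc", "f_measure", "csi", "ba",
    "fmi", "mk", "nlr", "fpr", "fnr",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    sen: float
    spec: float
    acc: float
    precision: float
    f_measure: float
    csi: float
    ba: float
    fmi: float
    mk: float
    nlr: float
    fpr: float
    fnr: float
    degenerate: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_from_labels(predicted: Sequence, truth: Sequence) -> ConfusionCounts:
    """Tally the 2x2 confusion table from binary label vectors."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs truth {t.shape}")
    if not (np.isin(p, [0, 1]).all() and np.isin(t, [0, 1]).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def _ratio(num: float, den: float, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metric_suite(c: ConfusionCounts) -> MetricReport:
    """Compute the full metric suite from confusion counts.

    Identities ``ba = (sen + spec)/2``, ``fpr = 1 - spec`` and
    ``fnr = 1 - sen`` hold exactly by construction.
    """
    deg: list = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sen = _ratio(tp, tp + fn, "sen", deg)
    spec = _ratio(tn, tn + fp, "spec", deg)
    acc = (tp + tn) / c.total
    precision = _ratio(tp, tp + fp, "precision", deg)
    f = _ratio(2 * precision * sen, precision + sen, "f_measure", deg)
    csi = _ratio(tp, tp + fn + fp, "csi", deg)
    ba = (sen + spec) / 2.0
    fmi = float(np.sqrt(precision * sen))
    npv = _ratio(tn, tn + fn, "npv", deg)
    mk = precision + npv - 1.0
    nlr = _ratio(1.0 - sen, spec, "nlr", deg)
    return MetricReport(
        sen=sen, spec=spec, acc=acc, precision=precision, f_measure=f,
        csi=csi, ba=ba, fmi=fmi, mk=mk, nlr=nlr,
        fpr=1.0 - spec, fnr=1.0 - sen, degenerate=deg,
    )


def write_comparison_csv(reports: dict, path) -> None:
    """Write a multi-run comparison CSV, one row per named report."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method"] + METRIC_COLUMNS)
        for name, report in reports.items():
            d = report.to_dict()
            writer.writerow([name] + [f"{d[k]:.6g}" for k in METRIC_COLUMNS])
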