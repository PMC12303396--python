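"""Registration-error assessment over the modified 10-5 montage.

Errors are per-label Euclidean distances between corresponding electrode
positions on two surfaces (after the rigid 10-20 alignment performed by
the pipeline).  Summaries follow the study schema: per-participant mean /
min / max / standard deviation across the 289 above-ear 10-5 positions,
grand means of those columns across participants, and per-position mean
and variance across participants for spatial error maps.

Standard deviations and variances are population statistics (divide by n);
the convention is fixed here for reproducibility.  Grand minimum/maximum
are reported both as means of the per-participant extremes and as global
extremes, since either reading of the summary table is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, LabelMismatchError, MixedMethodError
from .montage import MontagePointSet

__all__ = [
    "ErrorReport",
    "PositionStats",
    "pointwise_errors",
    "summarize",
    "grand_mean",
    "position_stats",
    "reports_to_frame",
]


@dataclass
class ErrorReport:
    """Per-participant (or grand-mean) error summary for one method."""

    per_label: dict
    mean: float
    minimum: float
    maximum: float
    std: float
    method_id: str
    participant_id: str
    n: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("min <= mean <= max violated")
        if self.std < 0:
            raise ValueError("std must be non-negative")

    def as_row(self) -> dict:
        row = {
            "method": self.method_id,
            "participant": self.participant_id,
            "mean_mm": self.mean,
            "min_mm": self.minimum,
            "max_mm": self.maximum,
            "std_mm": self.std,
            "n": self.n,
        }
        row.update(self.extra)
        return row


@dataclass
class PositionStats:
    """Per-position mean and variance of error across participants."""

    per_label_mean: dict
    per_label_variance: dict
    n_participants: int

    def __post_init__(self):
        if any(v < 0 for v in self.per_label_variance.values()):
            raise ValueError("variance must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.per_label_mean)
        return pd.DataFrame(
            {
                "label": labels,
                "mean_mm": [self.per_label_mean[l] for l in labels],
                "var_mm2": [self.per_label_variance[l] for l in labels],
                "n": self.n_participants,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pointwise_errors(a: MontagePointSet, b: MontagePointSet) -> dict:
    """Per-label Euclidean distance (mm) between corresponding positions."""
    if a.montage_id != b.montage_id:
        raise LabelMismatchError(
            f"montage ids differ: {a.montage_id!r} vs {b.montage_id!r}"
        )
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        raise LabelMismatchError(
            f"label sets differ (symmetric difference: {sorted(sa ^ sb)})",
            missing=sorted(sb - sa),
            extra=sorted(sa - sb),
        )
    db = b.as_dict()
    return {
        l: float(np.linalg.norm(p - db[l]))
        for l, p in zip(a.labels, a.positions)
    }


def summarize(errors: dict, method_id: str, participant_id: str) -> ErrorReport:
    """Mean / min / max / population-std summary of a per-label error map."""
    if not errors:
        raise EmptyInputError("empty error map")
    vals = np.asarray(list(errors.values()), dtype=np.float64)
    return ErrorReport(
        per_label=dict(errors),
        mean=float(vals.mean()),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        std=float(vals.std()),  # population (ddof=0)
        method_id=method_id,
        participant_id=participant_id,
    )


def grand_mean(reports: list) -> ErrorReport:
    """Across-participant grand mean for one method.

    Columns (mean/min/max/std) are averaged across the per-participant
    reports; global extremes are attached in ``extra`` alongside.
    """
    if not reports:
        raise EmptyInputError("no reports to average")
    methods = {r.method_id for r in reports}
    if len(methods) > 1:
        raise MixedMethodError(f"mixed methods in grand mean: {sorted(methods)}")
    if len(reports) == 1:
        return reports[0]
    return ErrorReport(
        per_label={},
        mean=float(np.mean([r.mean for r in reports])),
        minimum=float(np.mean([r.minimum for r in reports])),
        maximum=float(np.mean([r.maximum for r in reports])),
        std=float(np.mean([r.std for r in reports])),
        method_id=reports[0].method_id,
        participant_id="grand_mean",
        n=len(reports),
        extra={
            "global_min_mm": float(np.min([r.minimum for r in reports])),
            "global_max_mm": float(np.max([r.maximum for r in reports])),
        },
    )


def position_stats(error_maps: list) -> PositionStats:
    """Per-label mean and population variance across participants."""
    if not error_maps:
        raise EmptyInputError("no error maps")
    labels = list(error_maps[0])
    ref = set(labels)
    for m in error_maps[1:]:
        if set(m) != ref:
            raise LabelMismatchError(
                f"label sets differ across maps "
                f"(symmetric difference: {sorted(ref ^ set(m))})"
            )
    arr = np.asarray([[m[l] for l in labels] for m in error_maps], dtype=np.float64)
    return PositionStats(
        per_label_mean=dict(zip(labels, arr.mean(axis=0))),
        per_label_variance=dict(zip(labels, arr.var(axis=0))),  # population
        n_participants=len(error_maps),
    )


def reports_to_frame(reports: list) -> pd.DataFrame:
    """Delimited summary table mirroring the study's report schema."""
    return pd.DataFrame([r.as_row() for r in reports])


def write_reports_csv(reports: list, path) -> None:
    reports_to_frame(reports).to_csv(Path(path), index=False)
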