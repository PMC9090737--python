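"""F1 scoring of per-class prediction outcomes.

The unit of model performance throughout the pipeline is the F1 score,

    F1 = tp / (tp + (fp + fn) / 2),

the harmonic mean of precision and recall, chosen for its robustness to
class imbalance.  A multi-class test set yields one (tp, fp, fn) triple per
class; these are combined either macro (unweighted mean of per-class F1,
the default — test sets here are near-balanced by design) or micro (F1 of
the summed counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class ClassCounts:
    """Confusion counts for one class: true/false positives, false negatives."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn


@dataclass(frozen=True)
class PerformancePoint:
    """One (taxon, run, task size, F1) observation for curve fitting."""

    taxon: str
    run_index: int
    size: int
    f1: float


def f1_from_counts(counts: ClassCounts) -> float:
    """F1 = tp / (tp + (fp + fn)/2).  Undefined for all-zero counts."""
    if counts.total == 0:
        raise ValueError("F1 undefined: tp + fp + fn == 0")
    return counts.tp / (counts.tp + 0.5 * (counts.fp + counts.fn))


def aggregate_f1(per_class: Mapping[str, ClassCounts],
                 scheme: str = "macro") -> float:
    """Combine per-class confusion counts into one F1.

    macro: unweighted mean of per-class F1 over classes with any counts.
    micro: F1 of the element-wise summed counts.
    """
    scored = {cls: c for cls, c in per_class.items() if c.total > 0}
    if not scored:
        raise ValueError("no class with nonzero confusion counts")
    if scheme == "macro":
        return sum(f1_from_counts(c) for c in scored.values()) / len(scored)
    if scheme == "micro":
        pooled = ClassCounts(tp=sum(c.tp for c in scored.values()),
                             fp=sum(c.fp for c in scored.values()),
                             fn=sum(c.fn for c in scored.values()))
        return f1_from_counts(pooled)
    raise ValueError(f"unknown aggregation scheme {scheme!r}")


RESULTS_COLUMNS = ("taxon", "run", "size", "class", "tp", "fp", "fn")


def collect_points(results: pd.DataFrame,
                   scheme: str = "macro") -> list[PerformancePoint]:
    """Aggregate a per-class results table into performance points.

    ``results`` has one row per (taxon, run, size, class) with integer
    tp/fp/fn columns; each (taxon, run, size) cell yields one point.
    """
    missing = [c for c in RESULTS_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing column(s): {missing}")
    dup = results.duplicated(subset=["taxon", "run", "size", "class"])
    if dup.any():
        row = results[dup].iloc[0]
        raise ValueError(
            "duplicate result for "
            f"({row['taxon']}, run {row['run']}, size {row['size']}, "
            f"class {row['class']})")
    points = []
    for (taxon, run, size), grp in results.groupby(["taxon", "run", "size"],
                                                   sort=True):
        per_class = {
            r["class"]: ClassCounts(int(r["tp"]), int(r["fp"]), int(r["fn"]))
            for _, r in grp.iterrows()}
        points.append(PerformancePoint(taxon=str(taxon), run_index=int(run),
                                       size=int(size),
                                       f1=aggregate_f1(per_class, scheme)))
    return points


def points_by_taxon(points: list[PerformancePoint],
                    ) -> dict[str, list[PerformancePoint]]:
    grouped: dict[str, list[PerformancePoint]] = {}
    for p in points:
        grouped.setdefault(p.taxon, []).append(p)
    return grouped


def points_to_frame(points: list[PerformancePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.taxon, p.run_index, p.size, p.f1) for p in points],
        columns=["taxon", "run", "size", "f1"])


def points_from_frame(df: pd.DataFrame) -> list[PerformancePoint]:
    return [PerformancePoint(str(r.taxon), int(r.run), int(r.size),
                             float(r.f1))
            for r in df.itertuples(index=False)]
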