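"""Accuracy assessment: detection rates, error matrix, adjusted abundances.

Two complementary measurements: *tree detection* is assessed non-site-
specifically at plot level — classified and reference counts are compared per
plot and summed, with no tree-to-tree matching — and *species identification*
through a 4-class error matrix with producer's/user's/overall accuracies.
Detection rates also serve to adjust mapped abundances for over/under-
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CLASSES, TREE_CLASSES

__all__ = [
    "DetectionReport",
    "ErrorMatrix",
    "detection_rates",
    "adjust_counts",
    "build_error_matrix",
    "matrix_stats",
    "ground_truth_reference",
    "match_crowns_to_truth",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DetectionReport:
    """Per-class classified vs reference counts with detection rates (%)."""

    table: pd.DataFrame  # index: class + "total"; columns: classified, reference, difference, rate_pct

    @property
    def overall_rate(self) -> float:
        return float(self.table.at["total", "rate_pct"])

    def rate(self, cls: str) -> float:
        return float(self.table.at[cls, "rate_pct"])

    def rate_ratio(self, cls: str) -> float:
        """classified / reference, the adjustment factor for ``cls``."""
        return float(self.table.at[cls, "classified"] / self.table.at[cls, "reference"])

    def summary(self, digits: int = 5) -> str:
        t = self.table.copy()
        t["rate_pct"] = t["rate_pct"].map(lambda v: f"{v:.{digits}f}".rstrip("0").rstrip("."))
        return t.to_string()


def detection_rates(
    classified_counts: pd.DataFrame | dict,
    reference_counts: pd.DataFrame | dict,
    classes: tuple[str, ...] = TREE_CLASSES,
) -> DetectionReport:
    """Plot-level detection rates: ``100 * classified / reference`` per class.

    Inputs are either per-plot DataFrames (rows plots, columns classes) which
    are summed over plots first, or plain per-class count mappings. Every
    reported class must have a positive reference count.
    """

    def total(x) -> pd.Series:
        if isinstance(x, pd.DataFrame):
            return x.reindex(columns=list(classes), fill_value=0).sum(axis=0)
        return pd.Series({c: int(x[c]) for c in classes})

    cl = total(classified_counts)
    ref = total(reference_counts)
    if (ref <= 0).any():
        bad = list(ref.index[ref <= 0])
        raise ValueError(f"zero reference count for reported class(es): {bad}")
    rows = []
    for c in classes:
        rows.append(
            {
                "classified": int(cl[c]),
                "reference": int(ref[c]),
                "difference": int(cl[c] - ref[c]),
                "rate_pct": 100.0 * cl[c] / ref[c],
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(list(classes), name="class"))
    table.loc["total"] = {
        "classified": int(cl.sum()),
        "reference": int(ref.sum()),
        "difference": int(cl.sum() - ref.sum()),
        "rate_pct": 100.0 * cl.sum() / ref.sum(),
    }
    return DetectionReport(table=table)


def adjust_counts(
    raw_counts: dict, rates: "DetectionReport | dict", area_ha: float | None = None
) -> pd.DataFrame:
    """Detection-rate-adjusted abundances: ``round(raw / (rate/100))``.

    ``rates`` may be a :class:`DetectionReport` or a mapping class ->
    rate ratio (classified/reference). Rounding is half-up. With ``area_ha``
    the per-hectare densities of the adjusted counts are included.
    """
    rows = {}
    for cls, raw in raw_counts.items():
        if isinstance(rates, DetectionReport):
            ratio = rates.rate_ratio(cls)
        else:
            ratio = float(rates[cls])
        if not ratio > 0:
            raise ValueError(f"non-positive detection rate for {cls}")
        adj = _round_half_up(raw / ratio)
        rows[cls] = {"raw": int(raw), "adjusted": adj}
        if area_ha:
            rows[cls]["per_ha"] = adj / area_ha
    return pd.DataFrame(rows).T


@dataclass
class ErrorMatrix:
    """Square count matrix, rows = classified, columns = reference."""

    counts: pd.DataFrame  # index/columns: CLASSES order

    def __post_init__(self) -> None:
        c = self.counts
        if list(c.index) != list(c.columns):
            raise ValueError("error matrix must have identical row/column classes")
        if (c.to_numpy() < 0).any():
            raise ValueError("error matrix entries must be non-negative")

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_totals(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["row_total"] = self.row_totals()
        out.loc["column_total"] = out.sum(axis=0)
        return out


def build_error_matrix(
    samples: list[tuple[str, str]], classes: tuple[str, ...] = CLASSES
) -> ErrorMatrix:
    """Tally (reference, classified) label pairs into an error matrix."""
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for ref, cls in samples:
        if ref not in classes or cls not in classes:
            raise ValueError(f"unknown label in sample ({ref!r}, {cls!r})")
        counts.at[cls, ref] += 1
    return ErrorMatrix(counts=counts)


def matrix_stats(m: ErrorMatrix) -> pd.DataFrame:
    """Producer's/user's accuracy per class and the overall accuracy (%).

    Producer's accuracy is the diagonal over the reference (column) total,
    user's over the classified (row) total; overall is the trace over the
    grand total. Undefined ratios (zero totals) are NaN, not 0. Percentages
    are reported to 2 decimals in ``summary`` but kept at full precision here.
    """
    if m.grand_total <= 0:
        raise ValueError("empty error matrix")
    diag = pd.Series(np.diag(m.counts), index=m.counts.index, dtype=float)
    col = m.column_totals().astype(float)
    row = m.row_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = 100.0 * diag / col.replace(0, np.nan)
        users = 100.0 * diag / row.replace(0, np.nan)
    out = pd.DataFrame(
        {
            "reference_total": col.astype(int),
            "classified_total": row.astype(int),
            "number_correct": diag.astype(int),
            "producers_accuracy_pct": producers,
            "users_accuracy_pct": users,
        }
    )
    out.loc["overall"] = {
        "reference_total": m.grand_total,
        "classified_total": m.grand_total,
        "number_correct": int(diag.sum()),
        "producers_accuracy_pct": np.nan,
        "users_accuracy_pct": np.nan,
    }
    out.at["overall", "overall_accuracy_pct"] = 100.0 * diag.sum() / m.grand_total
    return out


def ground_truth_reference(truth, min_crown_m2: float = 4.0) -> tuple[pd.DataFrame, dict]:
    """Reference per-plot counts and per-tree class labels from ground truth.

    Applies the survey filters: crowns above ``min_crown_m2`` only, Algarrobo
    health grades 1-2 alive / 3 dead, Overo counted as present patches rather
    than trees. Returns (per-plot counts, {tree_id: reference class}).
    """
    from .synthetic import truth_plot_counts, truth_species_class

    counts = truth_plot_counts(truth, min_crown_m2=min_crown_m2)
    labels = {
        t.id: truth_species_class(t)
        for t in truth.trees
        if t.crown_spread_m2 > min_crown_m2
    }
    return counts, labels


def match_crowns_to_truth(crowns: list, truth) -> list[tuple[str, str]]:
    """Pair each classified crown with a reference label for the error matrix.

    A crown is matched to the truth tree with the largest footprint overlap;
    ties go to the nearest truth centroid. Crowns with no overlap and trees
    with no crown are omitted (the matrix needs label pairs in
    correspondence; detection rates already capture missed/spurious crowns).
    """
    from .synthetic import truth_species_class

    truth_by_id = {t.id: t for t in truth.trees}
    samples = []
    for crown in crowns:
        ids = truth.mask[crown.rows, crown.cols]
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        vals, cnts = np.unique(ids, return_counts=True)
        best = cnts.max()
        cand = vals[cnts == best]
        if cand.size > 1:
            cx, cy = crown.centroid_map
            cand = sorted(
                cand,
                key=lambda i: (cx - truth_by_id[i].centroid[0]) ** 2
                + (cy - truth_by_id[i].centroid[1]) ** 2,
            )
        tree = truth_by_id[int(cand[0])]
        samples.append((truth_species_class(tree), crown.label))
    return samples
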