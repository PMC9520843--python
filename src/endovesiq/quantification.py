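"""Per-field aggregation, condition comparison and ground-truth evaluation.

Counts are reported per field of view (the imaging unit over which the
experiment is replicated); two conditions are compared by an unpaired
two-sided two-sample t-test on the per-field counts — Welch's
unequal-variance variant by default, with the pooled-variance Student test
and a permutation test available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .synthetic import GroundTruth


def summarize_field(table: pd.DataFrame, condition_label: str = "") -> dict:
    """Collapse a classified vesicle table into one per-field count record.

    Produces ``n_vesicles``, and for every ``pos_*`` / ``copos_*`` column a
    count ``n_<col>`` and a fraction ``frac_<col>`` (fraction is ``None``
    for an empty table — undefined, not 0/0).
    """
    n = len(table)
    record: dict = {"condition": condition_label, "n_vesicles": n}
    flag_cols = [c for c in table.columns
                 if c.startswith("pos_") or c.startswith("copos_")]
    for col in flag_cols:
        k = int(table[col].sum()) if n else 0
        record[f"n_{col}"] = k
        record[f"frac_{col}"] = (k / n) if n else None
    return record


def summarize_fields(tables: list[pd.DataFrame],
                     condition_labels: list[str]) -> pd.DataFrame:
    """One summary row per field, in input order."""
    if len(tables) != len(condition_labels):
        raise ValueError("need one condition label per table")
    rows = [summarize_field(t, lbl) for t, lbl in zip(tables, condition_labels)]
    df = pd.DataFrame(rows)
    df.insert(0, "field", np.arange(len(df)))
    return df


@dataclass
class ComparisonResult:
    """Outcome of a two-condition comparison on per-field values."""

    test: str
    column: str
    statistic: float
    pvalue: float
    groups: dict = field(default_factory=dict)  # label -> {mean, sd, n}

    def to_dict(self) -> dict:
        return {"test": self.test, "column": self.column,
                "statistic": self.statistic, "pvalue": self.pvalue,
                "groups": self.groups}


def compare_conditions(
    summaries: pd.DataFrame,
    column: str,
    test: str = "welch",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> ComparisonResult:
    """Unpaired two-sided comparison of ``column`` between two conditions.

    ``test`` is ``"welch"`` (default), ``"student"`` (pooled variance) or
    ``"permutation"`` (difference of means, ``n_permutations`` resamples).
    Requires exactly two condition labels with at least two fields each.
    """
    if column not in summaries.columns:
        raise ValueError(f"column {column!r} not in summaries")
    labels = list(dict.fromkeys(summaries["condition"]))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {labels}")
    groups = []
    for lbl in labels:
        vals = summaries.loc[summaries["condition"] == lbl, column]
        vals = vals.dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(
                f"condition {lbl!r} has {len(vals)} usable fields; "
                "need at least 2 for a two-sample test"
            )
        groups.append(vals)
    a, b = groups

    if test in ("welch", "student"):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate zero-variance groups: equal means are maximally
            # non-significant, unequal means maximally significant
            equal = a.mean() == b.mean()
            statistic, pvalue = (0.0, 1.0) if equal else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(a, b, equal_var=(test == "student"))
            statistic, pvalue = float(res.statistic), float(res.pvalue)
    elif test == "permutation":
        rng = np.random.default_rng(seed)
        res = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent", alternative="two-sided",
            n_resamples=n_permutations, rng=rng,
        )
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        test=test, column=column, statistic=statistic, pvalue=pvalue,
        groups={lbl: {"mean": float(g.mean()), "sd": float(g.std(ddof=1)),
                      "n": int(len(g))}
                for lbl, g in zip(labels, groups)},
    )


@dataclass
class MatchResult:
    """Detections matched to simulator ground truth.

    ``pairs`` maps detected label -> ground-truth id. Precision is
    matched / detected (None when nothing was detected), recall is
    matched / truth (None when the truth is empty); ``rmse_px`` is the root
    mean square centroid distance over matched pairs.
    """

    pairs: dict[int, int]
    false_positive_labels: list[int]
    false_negative_ids: list[int]
    precision: float | None
    recall: float | None
    rmse_px: float | None

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_to_ground_truth(
    table: pd.DataFrame,
    truth: GroundTruth,
    max_dist: float,
) -> MatchResult:
    """Greedy nearest-neighbour matching of detections to true vesicles.

    Candidate (detection, truth) pairs within ``max_dist`` (centroid
    distance, px) are accepted in ascending distance order, each detection
    and each truth used at most once. Invariant to the ordering/labelling of
    the detections (ties broken by distance, then detection label, then
    truth id).
    """
    if not (max_dist > 0):
        raise ValueError("max_dist must be > 0")
    det_xy = table[["row", "col"]].to_numpy(dtype=float) if len(table) else \
        np.empty((0, 2))
    tru_xy = truth.vesicles[["row", "col"]].to_numpy(dtype=float) \
        if truth.n_vesicles else np.empty((0, 2))
    labels = table["label"].to_numpy() if len(table) else np.empty(0, dtype=int)
    ids = truth.vesicles["id"].to_numpy() if truth.n_vesicles else \
        np.empty(0, dtype=int)

    pairs: dict[int, int] = {}
    dists: list[float] = []
    if len(det_xy) and len(tru_xy):
        d = cdist(det_xy, tru_xy)
        di, tj = np.nonzero(d <= max_dist)
        order = np.lexsort((ids[tj], labels[di], d[di, tj]))
        used_det: set[int] = set()
        used_tru: set[int] = set()
        for k in order:
            i, j = int(di[k]), int(tj[k])
            if i in used_det or j in used_tru:
                continue
            used_det.add(i)
            used_tru.add(j)
            pairs[int(labels[i])] = int(ids[j])
            dists.append(float(d[i, j]))

    matched_det = set(pairs)
    matched_tru = set(pairs.values())
    fp = [int(l) for l in labels if int(l) not in matched_det]
    fn = [int(i) for i in ids if int(i) not in matched_tru]
    n_det, n_tru, n_match = len(labels), len(ids), len(pairs)
    return MatchResult(
        pairs=pairs,
        false_positive_labels=fp,
        false_negative_ids=fn,
        precision=(n_match / n_det) if n_det else None,
        recall=(n_match / n_tru) if n_tru else None,
        rmse_px=float(np.sqrt(np.mean(np.square(dists)))) if dists else None,
    )
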