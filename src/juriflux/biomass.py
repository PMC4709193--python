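"""Benchmark biomass map: stratify and multiply.

A jurisdiction-scale carbon-density map is built by (1) testing whether
candidate forest strata (disturbance x elevation x substrate classes)
hold statistically distinct aboveground biomass using lidar-footprint
samples — one-way ANOVA with Tukey's multiple comparison test, lumping
classes whose pairwise difference is non-significant — (2) ranking
competing stratification systems by their ANOVA F statistic, and
(3) assigning each forest pixel the mean footprint biomass of its final
stratum.

Footprint samples are a :class:`pandas.DataFrame` with at least a
``biomass`` column (MgC/ha) and one or more label columns; grid
coordinates ``x``/``y`` are carried when drawn from a landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumRecord",
    "StratificationResult",
    "anova_oneway",
    "evaluate_strata",
    "compare_stratifications",
    "fit_stratum_means",
    "build_benchmark_map",
]

ALPHA_DEFAULT = 0.05

#: elevation class edges in metres: closed on the left, open on the right;
#: a value exactly at an edge belongs to the upper class.
ELEVATION_EDGES_M = (100.0, 300.0, 900.0, 1500.0)


@dataclass
class StratumRecord:
    """Mean aboveground live carbon of one final biomass stratum."""

    stratum: Hashable            # stratum id h
    mean: float                  # Cd_h, MgC/ha
    sem: float                   # MgC/ha
    n: int
    labels: tuple = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("stratum sample count must be >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")
        if not np.isfinite(self.mean):
            raise ValueError("stratum mean must be finite")


@dataclass
class StratificationResult:
    """Outcome of iterative ANOVA/Tukey stratum evaluation."""

    assignment: dict              # candidate label -> final stratum label
    strata: list                  # final stratum labels, order of first appearance
    f_statistic: float            # one-way ANOVA F over the final strata
    p_value: float
    lump_log: list = field(default_factory=list)   # (label_a, label_b, p) merges
    tukey_p: pd.DataFrame | None = None            # final pairwise p-values
    degenerate: bool = False

    @property
    def n_strata(self) -> int:
        return len(self.strata)


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    Returns ``(F, p)``. Kept as in-package arithmetic so tests can
    cross-check it against an independent routine.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        return float("nan"), float("nan")
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    if n_total <= k:
        return float("nan"), float("nan")
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        # degenerate within-group variance
        if ss_between == 0.0:
            return float("nan"), float("nan")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, p


def _group_values(samples: pd.DataFrame, by) -> dict:
    """Map group label -> biomass values; `by` is a column, list of
    columns, or an explicit label array."""
    if isinstance(by, str):
        keys = samples[by]
    elif isinstance(by, (list, tuple)) and all(isinstance(c, str) for c in by):
        keys = samples[list(by)].apply(tuple, axis=1)
    else:
        keys = pd.Series(list(by), index=samples.index)
    out: dict = {}
    for label, grp in samples.groupby(keys, sort=False):
        out[label] = grp["biomass"].to_numpy(dtype=float)
    return out


def evaluate_strata(
    samples: pd.DataFrame,
    by="stratum",
    alpha: float = ALPHA_DEFAULT,
) -> StratificationResult:
    """Lump candidate strata until every retained pair differs.

    Iteratively runs Tukey's HSD over the current strata; while any pair
    is non-significant at ``alpha``, the non-significant pair with the
    smallest absolute mean difference is merged (deterministic greedy
    order) and the test is recomputed. Merged labels are joined with
    ``"+"``.
    """
    groups = _group_values(samples, by)
    if len(groups) < 2:
        raise ValueError("need at least 2 candidate strata")
    small = [lbl for lbl, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"candidate strata with < 2 samples: {small}")

    # candidate -> current merged label
    assignment = {lbl: str(lbl) for lbl in groups}
    current = {str(lbl): v for lbl, v in groups.items()}
    lump_log: list[tuple[str, str, float]] = []

    pooled = np.concatenate(list(current.values()))
    if np.ptp(pooled) == 0.0:
        # all samples identical: no variance to support any split
        merged_label = "+".join(current)
        return StratificationResult(
            assignment={lbl: merged_label for lbl in assignment},
            strata=[merged_label],
            f_statistic=float("nan"), p_value=float("nan"),
            lump_log=[], degenerate=True,
        )

    while len(current) > 1:
        labels = list(current)
        res = stats.tukey_hsd(*[current[l] for l in labels])
        worst: tuple[float, str, str, float] | None = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = float(res.pvalue[i, j])
                if p > alpha:
                    diff = abs(float(np.mean(current[labels[i]]))
                               - float(np.mean(current[labels[j]])))
                    cand = (diff, labels[i], labels[j], p)
                    if worst is None or cand[0] < worst[0]:
                        worst = cand
        if worst is None:
            break
        _, a, b, p = worst
        merged = f"{a}+{b}"
        current[merged] = np.concatenate([current.pop(a), current.pop(b)])
        for lbl, cur in assignment.items():
            if cur in (a, b):
                assignment[lbl] = merged
        lump_log.append((a, b, p))

    final_labels = list(current)
    f, p = anova_oneway([current[l] for l in final_labels])
    tukey_df = None
    if len(final_labels) > 1:
        res = stats.tukey_hsd(*[current[l] for l in final_labels])
        tukey_df = pd.DataFrame(res.pvalue, index=final_labels,
                                columns=final_labels)
    return StratificationResult(
        assignment=assignment, strata=final_labels,
        f_statistic=f, p_value=p, lump_log=lump_log, tukey_p=tukey_df,
    )


def compare_stratifications(
    samples: pd.DataFrame,
    stratifications: Mapping[str, object],
) -> pd.DataFrame:
    """Rank competing stratification systems by one-way ANOVA F.

    ``stratifications`` maps a system name to a label column (or label
    array over samples). Returns a DataFrame indexed by system with
    columns ``n_classes``, ``F``, ``p``, sorted by F descending; a
    system with a single class has undefined F (NaN) and sorts last.
    """
    rows = []
    for name, by in stratifications.items():
        groups = _group_values(samples, by)
        f, p = anova_oneway(list(groups.values()))
        rows.append({"system": name, "n_classes": len(groups), "F": f, "p": p})
    out = pd.DataFrame(rows).set_index("system")
    return out.sort_values("F", ascending=False, na_position="last")


def fit_stratum_means(
    samples: pd.DataFrame,
    by="stratum",
) -> list[StratumRecord]:
    """Per-stratum arithmetic mean, SEM = sd/sqrt(n), and n.

    The sd is the root-mean-square deviation from the stratum mean
    (population convention), so two samples {100, 120} give SEM
    10/sqrt(2) ~ 7.07. Strata present in the grouping but empty after
    filtering are excluded with a warning; single-valued strata get
    SEM 0.
    """
    groups = _group_values(samples, by)
    records = []
    for label, values in groups.items():
        if len(values) == 0:
            warnings.warn(f"stratum {label!r} has no samples; excluded")
            continue
        n = len(values)
        mean = float(values.mean())
        sem = float(values.std(ddof=0) / np.sqrt(n))
        records.append(StratumRecord(stratum=label, mean=mean, sem=sem, n=n))
    return records


def records_frame(records: Sequence[StratumRecord]) -> pd.DataFrame:
    """StratumRecords as a table (class label, mean, SEM, n)."""
    return pd.DataFrame(
        [{"stratum": r.stratum, "mean_MgC_ha": r.mean, "sem_MgC_ha": r.sem,
          "n": r.n} for r in records]
    ).set_index("stratum")


def build_benchmark_map(
    stratum_raster: np.ndarray,
    records: Sequence[StratumRecord] | Mapping[Hashable, float],
    nodata: float = np.nan,
) -> np.ndarray:
    """Assign every forest pixel its stratum's mean carbon density.

    ``stratum_raster`` holds integer stratum ids with 0 = non-forest
    (mapped to ``nodata``). Every nonzero id present in the raster must
    have a record; unmapped ids raise with the offending ids listed.
    """
    if isinstance(records, Mapping):
        means = {h: float(v) for h, v in records.items()}
    else:
        means = {r.stratum: r.mean for r in records}
    ids = np.unique(stratum_raster)
    ids = ids[ids != 0]
    missing = [int(h) for h in ids if h not in means]
    if missing:
        raise KeyError(f"stratum ids without a biomass record: {missing}")
    out = np.full(stratum_raster.shape, nodata, dtype=float)
    for h in ids:
        out[stratum_raster == h] = means[h]
    return out


def elevation_class(elevation_m) -> np.ndarray:
    """Elevation class index from metres, edges at 100/300/900/1500 m.

    Intervals are closed on the left and open on the right; a value
    exactly at an edge goes to the upper class. Returns 0..4.
    """
    return np.searchsorted(np.asarray(ELEVATION_EDGES_M), np.asarray(elevation_m),
                           side="right")
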