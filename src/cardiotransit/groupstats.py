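"""Group-level statistics over per-cell calcium-transient summaries.

Comparisons use the pooled-variance (Student's) two-sample t-test on
per-cell values; nested structure over differentiation batches is
summarised by a one-way random-effects (Model II) ANOVA with
expected-mean-square variance-component estimates.  A ddCt utility covers
relative qPCR quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "Comparison",
    "GroupResult",
    "DdctResult",
    "students_t",
    "random_effects_anova",
    "compare_groups",
    "compute_ddct",
    "METRIC_COLUMNS",
]

#: per-cell metric columns produced by the transient analysis
METRIC_COLUMNS = ("amplitude", "rise_time_ms", "decay50_ms")


def students_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance Student's t-test, two-tailed, df = nA + nB - 2.

    With zero pooled variance: equal means give (0, 1) by convention;
    unequal means are flagged as an error (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


@dataclass(frozen=True)
class AnovaResult:
    """One-way random-effects ANOVA decomposition."""

    sigma2_between: float  # truncated at 0
    sigma2_within: float
    f_stat: float
    p_value: float
    ms_between: float
    ms_within: float
    n0: float  # unbalanced-design coefficient in E[MS_between]


def random_effects_anova(
    values: np.ndarray, batch_labels: Sequence
) -> AnovaResult:
    """Model II one-way ANOVA via expected mean squares.

    sigma2_within = MS_within; sigma2_between = max(0, (MS_between -
    MS_within) / n0) with n0 = (N - sum n_i^2 / N) / (k - 1); F is the MS
    ratio with (k-1, N-k) df.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(batch_labels)
    if v.size != labels.size:
        raise ValueError("values and batch_labels must align")
    groups = [v[labels == b] for b in np.unique(labels)]
    k = len(groups)
    if k < 2:
        raise ValueError("random-effects ANOVA needs at least two batches")
    n = np.array([g.size for g in groups])
    if not np.any(n >= 2):
        raise ValueError("at least one batch must hold two or more cells")
    N = int(n.sum())
    grand = v.mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - float(np.sum(n**2)) / N) / (k - 1)
    sigma2_within = ms_within
    sigma2_between = max(0.0, (ms_between - ms_within) / n0)
    if ms_within > 0:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, k - 1, N - k))
    else:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    return AnovaResult(
        sigma2_between=sigma2_between,
        sigma2_within=sigma2_within,
        f_stat=float(f),
        p_value=p,
        ms_between=ms_between,
        ms_within=ms_within,
        n0=n0,
    )


@dataclass(frozen=True)
class Comparison:
    group_a: str
    group_b: str
    metric: str
    t_statistic: float
    p_two_tailed: float


@dataclass(frozen=True)
class GroupResult:
    group_label: str
    n_cells: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    comparisons: tuple[Comparison, ...] = ()
    anova: Mapping[str, AnovaResult] = field(default_factory=dict)


def _metric_values(cells: pd.DataFrame, group: str, metric: str) -> np.ndarray:
    return cells.loc[cells["group"] == group, metric].to_numpy(dtype=float)


def compare_groups(
    cells: pd.DataFrame,
    plan: Mapping,
    alpha: float = 0.05,
    use_batch_means: bool = False,
) -> tuple[list[GroupResult], dict[str, bool], pd.DataFrame]:
    """Run the planned pairwise t-tests and the rescue assessment.

    ``cells`` holds one row per cell with columns ``group, batch`` and the
    metric columns.  ``plan`` is ``{"pairs": [[A, B], ...], "rescue":
    {"treated_ko": ..., "reference": ..., "treated_reference": ...}}``.  The
    rescue flag per metric is true when treated-KO vs reference is
    non-significant while treated-reference vs reference is significant,
    i.e. the knock-out abolishes the treatment effect.

    Returns per-group results, the rescue flags, and a tidy table of all
    comparisons.  ``use_batch_means`` collapses cells to batch means first
    (a conservative alternative for nested data).
    """
    present = set(cells["group"])
    data = cells
    if use_batch_means:
        data = (
            cells.groupby(["group", "batch"], as_index=False)[list(METRIC_COLUMNS)]
            .mean()
        )

    def values(group: str, metric: str) -> np.ndarray:
        if group not in present:
            raise ValueError(f"group {group!r} missing from the cell table")
        return _metric_values(data, group, metric)

    rows = []
    comparisons_by_group: dict[str, list[Comparison]] = {g: [] for g in present}
    for pair in plan.get("pairs", []):
        a, b = pair
        for metric in METRIC_COLUMNS:
            t, p = students_t(values(a, metric), values(b, metric))
            comp = Comparison(a, b, metric, t, p)
            comparisons_by_group[a].append(comp)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "metric": metric,
                    "t": t,
                    "p": p,
                    "significant": p < alpha,
                }
            )

    rescue_flags: dict[str, bool] = {}
    rescue = plan.get("rescue")
    if rescue:
        treated_ko = rescue["treated_ko"]
        reference = rescue["reference"]
        treated_ref = rescue["treated_reference"]
        for metric in METRIC_COLUMNS:
            _, p_ko = students_t(values(treated_ko, metric), values(reference, metric))
            _, p_ref = students_t(values(treated_ref, metric), values(reference, metric))
            rescue_flags[metric] = (p_ko >= alpha) and (p_ref < alpha)
            rows.append(
                {
                    "group_a": treated_ko,
                    "group_b": reference,
                    "metric": metric,
                    "t": np.nan,
                    "p": p_ko,
                    "significant": p_ko < alpha,
                }
            )

    results = []
    for g in sorted(present):
        sub = cells[cells["group"] == g]
        anova = {}
        if sub["batch"].nunique() >= 2 and sub.groupby("batch").size().max() >= 2:
            for metric in METRIC_COLUMNS:
                anova[metric] = random_effects_anova(
                    sub[metric].to_numpy(), sub["batch"].to_numpy()
                )
        results.append(
            GroupResult(
                group_label=g,
                n_cells=len(sub),
                means={m: float(sub[m].mean()) for m in METRIC_COLUMNS},
                sds={m: float(sub[m].std(ddof=1)) for m in METRIC_COLUMNS},
                comparisons=tuple(comparisons_by_group[g]),
                anova=anova,
            )
        )
    return results, rescue_flags, pd.DataFrame(rows)


@dataclass(frozen=True)
class DdctResult:
    """Relative qPCR quantification by the ddCt method."""

    delta_delta_ct: float
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def compute_ddct(
    ct_target: float,
    ct_refs: Sequence[float],
    ct_target_calibrator: float,
    ct_refs_calibrator: Sequence[float],
) -> DdctResult:
    """ddCt: dCt = Ct_target - mean(Ct_refs) per condition; fold = 2^-ddCt.

    Reference genes (e.g. 18S rRNA and GAPDH) are averaged within each
    condition.
    """
    refs = np.asarray(ct_refs, dtype=float)
    refs_cal = np.asarray(ct_refs_calibrator, dtype=float)
    if refs.size == 0 or refs_cal.size == 0:
        raise ValueError("reference Ct list must not be empty")
    all_ct = np.concatenate([refs, refs_cal, [ct_target, ct_target_calibrator]])
    if not np.all(np.isfinite(all_ct)):
        raise ValueError("all Ct values must be finite")
    d_sample = ct_target - refs.mean()
    d_cal = ct_target_calibrator - refs_cal.mean()
    ddct = d_sample - d_cal
    return DdctResult(delta_delta_ct=float(ddct), fold_change=float(2.0 ** (-ddct)))
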