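"""Subject-adjusted amplitude-connectivity correlations and permutation tests.

The central statistic is the partial Pearson correlation between node
amplitude and a node graph measure with the subject identity partialled out:
observations (one per node per subject) are residualized on subject
indicator contrasts, which is equivalent to centering x and y within each
subject, and the Pearson coefficient of the residuals is reported with
``df = N - (S - 1) - 2`` where S is the number of subjects.  Group
differences of these coefficients are tested by permuting the subject-to-
group assignment (5 vs 5 without replacement within each draw) and
comparing the observed difference against the 2.5-97.5 percentile interval
of the permutation differences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CouplingResult",
    "PermutationResult",
    "partial_correlation",
    "coupling_profile",
    "coupling_frame",
    "permutation_group_difference",
    "amplitude_group_ttest",
    "demographics_ttests",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class CouplingResult:
    """Partial amplitude-measure correlation for one (group, stage, m) cell."""

    group: str
    stage: str
    m: int
    measure: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_obs: int
    n_subjects: int
    significant: bool
    valid: bool = True


@dataclass
class PermutationResult:
    """Observed group difference against its permutation percentile interval."""

    observed_diff: float
    perm_ci_low: float
    perm_ci_high: float
    n_perm: int
    seed: int | None
    significant: bool
    r_by_group: Dict[str, float]


def _center_within(values: np.ndarray, subject: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for s in np.unique(subject):
        sel = subject == s
        out[sel] = values[sel] - values[sel].mean()
    return out


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    subject: Sequence[Hashable],
    alpha: float = 0.05,
) -> Tuple[float, Tuple[float, float], float]:
    """Pearson correlation of x and y with the subject effect removed.

    Returns ``(r, (ci_low, ci_high), p)``.  The confidence interval is a
    Fisher-z interval with the subject-adjusted degrees of freedom
    ``df = N - (S - 1) - 2``; the two-sided p-value uses the t distribution
    on the same df.  A zero residual variance yields ``(nan, (nan, nan),
    nan)`` — an undefined, flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (len(x) == len(y) == len(subject)):
        raise ValueError("x, y and subject must have equal length")
    n = len(x)
    n_subjects = len(np.unique(subject))
    df = n - (n_subjects - 1) - 2
    if df < 3:
        raise ValueError("need at least 3 residual degrees of freedom")
    xr = _center_within(x, subject)
    yr = _center_within(y, subject)
    sxx = xr @ xr
    syy = yr @ yr
    if sxx <= 0 or syy <= 0:
        return math.nan, (math.nan, math.nan), math.nan
    r = float((xr @ yr) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, (r, r), 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    se = 1.0 / math.sqrt(max(df - 1, 1))
    zr = math.atanh(r)
    ci = (math.tanh(zr - zcrit * se), math.tanh(zr + zcrit * se))
    return r, ci, float(p)


def coupling_profile(
    tables: pd.DataFrame,
    measure: str,
    m_values: Sequence[int] | None = None,
    stages: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> List[CouplingResult]:
    """Amplitude-measure partial correlations per (group, stage, m).

    ``tables`` is a long-format frame with columns ``group, subject, stage,
    m, amplitude, <measure>`` (one row per node observation).  Cells whose
    (stage, m) combination is absent are skipped with a log entry.
    """
    required = {"group", "subject", "stage", "m", "amplitude", measure}
    missing = required - set(tables.columns)
    if missing:
        raise ValueError(f"tables is missing columns: {sorted(missing)}")
    if m_values is None:
        m_values = sorted(tables["m"].unique())
    if stages is None:
        stages = sorted(tables["stage"].unique())
    results: List[CouplingResult] = []
    for group, gdf in tables.groupby("group", sort=True):
        for stage in stages:
            for m in m_values:
                cell = gdf[(gdf["stage"] == stage) & (gdf["m"] == m)]
                cell = cell.dropna(subset=["amplitude", measure])
                if cell.empty:
                    log.info(
                        "coupling_profile: no data for group=%s stage=%s m=%s",
                        group, stage, m,
                    )
                    continue
                try:
                    r, ci, p = partial_correlation(
                        cell["amplitude"], cell[measure], cell["subject"], alpha
                    )
                except ValueError:
                    log.info(
                        "coupling_profile: too few dof for group=%s stage=%s m=%s",
                        group, stage, m,
                    )
                    continue
                valid = not math.isnan(r)
                results.append(
                    CouplingResult(
                        group=group,
                        stage=stage,
                        m=int(m),
                        measure=measure,
                        r=r,
                        ci_low=ci[0],
                        ci_high=ci[1],
                        p=p,
                        n_obs=len(cell),
                        n_subjects=cell["subject"].nunique(),
                        significant=valid and p < alpha,
                        valid=valid,
                    )
                )
    return results


def coupling_frame(results: Sequence[CouplingResult]) -> pd.DataFrame:
    """Long-format frame of coupling results (mirrors the plotting input)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "stage": r.stage,
                "m": r.m,
                "measure": r.measure,
                "r": r.r,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "significant": r.significant,
                "n_obs": r.n_obs,
                "n_subjects": r.n_subjects,
            }
            for r in results
        ]
    )


def _subject_sums(
    data: Mapping[Hashable, Tuple[np.ndarray, np.ndarray]]
) -> Dict[Hashable, Tuple[float, float, float]]:
    sums = {}
    for s, (x, y) in data.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        xc = x - x.mean()
        yc = y - y.mean()
        sums[s] = (float(xc @ yc), float(xc @ xc), float(yc @ yc))
    return sums


def _pooled_r(sums, subjects) -> float:
    sxy = sum(sums[s][0] for s in subjects)
    sxx = sum(sums[s][1] for s in subjects)
    syy = sum(sums[s][2] for s in subjects)
    if sxx <= 0 or syy <= 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def permutation_group_difference(
    data: Mapping[Hashable, Tuple[np.ndarray, np.ndarray]],
    groups: Mapping[Hashable, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test on the inter-group difference of partial correlations.

    ``data`` maps each subject to its (x, y) node vectors; ``groups`` maps
    subjects to one of two group labels.  Each permutation reassigns the
    subjects to two groups of the original sizes without replacement and
    recomputes both subject-adjusted coefficients and their difference
    (first group minus second, in sorted label order).  The observed
    difference is compared against the 2.5-97.5 percentile interval of the
    ``n_perm`` permutation differences.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g1 = sorted(s for s in data if groups[s] == labels[0])
    g2 = sorted(s for s in data if groups[s] == labels[1])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    sums = _subject_sums(data)
    r1 = _pooled_r(sums, g1)
    r2 = _pooled_r(sums, g2)
    observed = r1 - r2

    rng = np.random.default_rng(seed)
    subjects = np.array(g1 + g2, dtype=object)
    n1 = len(g1)
    diffs = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(subjects)
        diffs[b] = _pooled_r(sums, perm[:n1]) - _pooled_r(sums, perm[n1:])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return PermutationResult(
        observed_diff=float(observed),
        perm_ci_low=float(lo),
        perm_ci_high=float(hi),
        n_perm=n_perm,
        seed=seed,
        significant=bool(observed < lo or observed > hi),
        r_by_group={labels[0]: float(r1), labels[1]: float(r2)},
    )


def exhaustive_group_difference(
    data: Mapping[Hashable, Tuple[np.ndarray, np.ndarray]],
    groups: Mapping[Hashable, str],
) -> Tuple[float, np.ndarray]:
    """All distinct 5/5-style reassignments (observed diff, diff distribution).

    For a 5-vs-5 design there are C(10,5) = 252 distinct assignments; this
    enumerates them exactly and serves as the oracle for the sampled test.
    """
    labels = sorted(set(groups.values()))
    g1 = sorted(s for s in data if groups[s] == labels[0])
    g2 = sorted(s for s in data if groups[s] == labels[1])
    sums = _subject_sums(data)
    all_subjects = g1 + g2
    n1 = len(g1)
    observed = _pooled_r(sums, g1) - _pooled_r(sums, g2)
    diffs = []
    for combo in itertools.combinations(all_subjects, n1):
        rest = [s for s in all_subjects if s not in combo]
        diffs.append(_pooled_r(sums, combo) - _pooled_r(sums, rest))
    return float(observed), np.array(diffs)


def amplitude_group_ttest(
    z_scores: pd.DataFrame,
    groups: Mapping[Hashable, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-node permutation t-tests of amplitude z-scores between two groups.

    ``z_scores`` has one row per subject and one column per node.  The
    two-sample t statistic (pooled variance) is recomputed under ``n_perm``
    random relabelings; the two-sided p-value per node is
    ``(1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)``.  Nodes with zero
    pooled variance get t = 0 and p = 1.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    mask1 = np.array([groups[s] == labels[0] for s in z_scores.index])
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    values = z_scores.to_numpy(dtype=float)

    def tstat(m1: np.ndarray) -> np.ndarray:
        a = values[m1]
        b = values[~m1]
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        denom = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / np.where(denom > 0, denom, 1.0), 0.0)
        return t

    t_obs = tstat(mask1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(len(mask1))
        exceed += np.abs(tstat(mask1[perm])) >= np.abs(t_obs)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.abs(t_obs) == 0, 1.0, p)
    return pd.DataFrame({"t": t_obs, "p": p}, index=z_scores.columns)


def plot_coupling_continuum(frame: pd.DataFrame, path, title: str = "") -> None:
    """Coefficient-vs-maximum-island-size plot, one panel per stage.

    ``frame`` is the long-format output of :func:`coupling_frame`; groups
    are overlaid with their confidence ribbons, significant coefficients
    marked with asterisks.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = sorted(frame["stage"].unique())
    fig, axes = plt.subplots(
        1, max(len(stages), 1), figsize=(3.2 * max(len(stages), 1), 3.0),
        sharey=True, squeeze=False,
    )
    for ax, stage in zip(axes[0], stages):
        sub = frame[frame["stage"] == stage]
        for group, gdf in sub.groupby("group"):
            gdf = gdf.sort_values("m")
            ax.plot(gdf["m"], gdf["r"], marker="o", label=str(group))
            ax.fill_between(gdf["m"], gdf["ci_low"], gdf["ci_high"], alpha=0.2)
            sig = gdf[gdf["significant"]]
            ax.plot(sig["m"], sig["r"], linestyle="none", marker="*", markersize=10)
        ax.axhline(0.0, color="grey", linewidth=0.5)
        ax.set_title(str(stage))
        ax.set_xlabel("maximum island size m")
    axes[0][0].set_ylabel("partial r")
    axes[0][0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def demographics_ttests(table: pd.DataFrame) -> pd.Series:
    """Paired two-tailed t-tests across matched pairs for age, education and AQ.

    ``table`` must carry ``group``, ``pair_index`` and the three variables;
    both groups must have the same number of subjects, matched by
    ``pair_index``.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    a = table[table["group"] == groups[0]].sort_values("pair_index")
    b = table[table["group"] == groups[1]].sort_values("pair_index")
    if len(a) != len(b):
        raise ValueError("groups must have equal sizes (matched pairs)")
    if not np.array_equal(a["pair_index"].to_numpy(), b["pair_index"].to_numpy()):
        raise ValueError("pair_index values must match across groups")
    out = {}
    for var in ("age_years", "education_years", "AQ"):
        res = stats.ttest_rel(a[var].to_numpy(), b[var].to_numpy())
        out[var] = float(res.pvalue)
    return pd.Series(out)
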