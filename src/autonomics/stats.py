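"""Group-comparison and correlation layer.

Non-parametric pipeline for three-group cohort tables: Kruskal-Wallis
with a post hoc Dunn test (pairwise significance judged against a
Bonferroni-corrected alpha, 0.05/3 = 0.01667 for three groups), a
Spearman correlation screen retained at p < 0.01, chi-square tests for
categorical variables, and descriptive medians with interquartile ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

logger = logging.getLogger(__name__)

HADS_RANGE = (0, 21)
MFI_RANGE = (4, 20)


@dataclass
class Subject:
    """Covariates of one study participant."""

    subject_id: str
    group: str                      # HC | MECFS | PCC
    age: float                      # years
    sex: str
    bmi: float                      # kg/m^2
    mfi: dict                       # five MFI-20 domain scores, 4-20 each
    hads_a: int                     # 0-21
    hads_d: int                     # 0-21
    ipaq_total: float               # MET-min/week
    criteria_flags: dict | None = None  # patient groups only

    def __post_init__(self) -> None:
        for name, score in (("hads_a", self.hads_a), ("hads_d", self.hads_d)):
            if not HADS_RANGE[0] <= score <= HADS_RANGE[1]:
                raise ValueError(f"{name}={score} outside instrument range 0-21")
        for domain, score in self.mfi.items():
            if not MFI_RANGE[0] <= score <= MFI_RANGE[1]:
                raise ValueError(f"MFI {domain}={score} outside instrument range 4-20")
        if self.group == "HC" and self.criteria_flags is not None:
            raise ValueError("criteria flags apply to patient groups only")


def hads_category(score: int) -> str:
    """HADS subscale interpretation: 0-7 normal, 8-10 borderline,
    11 or more a probable case of anxiety/depression."""
    if not (isinstance(score, (int, np.integer)) and 0 <= score <= 21):
        raise ValueError(f"HADS subscale score must be an integer in 0-21, got {score!r}")
    if score <= 7:
        return "normal"
    if score <= 10:
        return "borderline"
    return "probable"


@dataclass
class GroupComparison:
    """Kruskal-Wallis H with Dunn pairwise decisions for one variable."""

    variable: str
    kw_h: float
    kw_p: float
    dunn_p: dict = field(default_factory=dict)       # pair -> unadjusted p
    dunn_z: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)  # pair -> bool
    corrected_alpha: float = float("nan")

    def __post_init__(self) -> None:
        for p in [self.kw_p, *self.dunn_p.values()]:
            if np.isfinite(p) and not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    variable: str = "",
    family_alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal-Wallis test with Dunn post hoc z-tests for all pairs.

    Pairwise significance follows the corrected-alpha convention: a pair
    is significant iff its unadjusted Dunn p falls below
    ``family_alpha / n_pairs`` (0.01667 for three groups at 0.05).
    Dunn z statistics use average ranks over the pooled sample with the
    standard tie correction.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    for g, v in zip(names, values):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        pairs = list(combinations(names, 2))
        alpha = family_alpha / len(pairs)
        return GroupComparison(
            variable=variable, kw_h=0.0, kw_p=1.0,
            dunn_p={p: 1.0 for p in pairs}, dunn_z={p: 0.0 for p in pairs},
            significant={p: False for p in pairs}, corrected_alpha=alpha,
        )
    kw_h, kw_p = sst.kruskal(*values)

    ranks = sst.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    start = 0
    for g, v in zip(names, values):
        mean_ranks[g] = float(np.mean(ranks[start:start + len(v)]))
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    alpha = family_alpha / len(pairs)
    dunn_p, dunn_z, significant = {}, {}, {}
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sst.norm.sf(abs(z))
        dunn_z[(a, b)] = z
        dunn_p[(a, b)] = p
        significant[(a, b)] = p < alpha
    return GroupComparison(
        variable=variable, kw_h=float(kw_h), kw_p=float(kw_p),
        dunn_p=dunn_p, dunn_z=dunn_z, significant=significant,
        corrected_alpha=alpha,
    )


def spearman_screen(
    physio: pd.DataFrame,
    covariates: pd.DataFrame,
    physio_vars: list[str] | None = None,
    covariate_vars: list[str] | None = None,
    p_thresh: float = 0.01,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group Spearman correlations, retained at ``p < p_thresh``.

    ``physio`` and ``covariates`` are merged on ``subject_id``; the screen
    runs per group over every physiological-variable x covariate pair and
    keeps only the rows passing the threshold (the convention of reporting
    a correlation table at p < 0.01).  Constant variables are skipped with
    a log entry.
    """
    merged = physio.merge(covariates, on="subject_id", suffixes=("", "_cov"))
    physio_vars = physio_vars or [c for c in physio.columns
                                  if c not in ("subject_id", group_col)]
    covariate_vars = covariate_vars or [c for c in covariates.columns
                                        if c not in ("subject_id", group_col)]
    rows = []
    for group, sub in merged.groupby(group_col):
        if len(sub) < 5:
            raise ValueError(f"group {group!r} has fewer than 5 subjects")
        for pv in physio_vars:
            for cv in covariate_vars:
                x = pd.to_numeric(sub[pv], errors="coerce")
                y = pd.to_numeric(sub[cv], errors="coerce")
                ok = x.notna() & y.notna()
                if ok.sum() < 5:
                    continue
                if x[ok].nunique() < 2 or y[ok].nunique() < 2:
                    logger.info("spearman_screen: %s/%s vs %s constant, skipped",
                                group, pv, cv)
                    continue
                r, p = sst.spearmanr(x[ok], y[ok])
                if p < p_thresh:
                    rows.append({"group": group, "variable": pv,
                                 "covariate": cv, "spearman_r": float(r),
                                 "p": float(p)})
    return pd.DataFrame(rows, columns=["group", "variable", "covariate",
                                       "spearman_r", "p"])


def categorical_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square test (no continuity correction) on a 2-way count
    table; zero-margin rows/columns are dropped with a warning."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a 2-way count table")
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("categorical_test: dropping zero-margin rows/columns")
        counts = counts[row_ok][:, col_ok]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table degenerate after dropping zero margins")
    stat, p, _, _ = sst.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def criteria_fraction(cohort_frame: pd.DataFrame, group: str, flag: str) -> float:
    """Percentage of a group meeting a diagnostic-criteria flag, rounded to
    one decimal (e.g. 14 of 29 -> 48.3)."""
    sub = cohort_frame[cohort_frame["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} is empty")
    met = sub[flag].astype(bool).sum()
    return round(100.0 * float(met) / len(sub), 1)


def median_iqr_table(
    frame: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Descriptive summary in the conventional form: median (P25-P75) per
    group, with the Kruskal-Wallis/Dunn comparison per variable."""
    rows = []
    for var in variables:
        groups = {g: sub[var].dropna().to_numpy()
                  for g, sub in frame.groupby(group_col)}
        comp = kruskal_dunn(groups, variable=var)
        row = {"variable": var, "kw_p": comp.kw_p}
        for g, v in groups.items():
            q25, q50, q75 = np.percentile(v, [25, 50, 75])
            row[g] = f"{q50:.2f} ({q25:.2f}-{q75:.2f})"
        for pair, sig in comp.significant.items():
            row[f"dunn_p {pair[0]} vs {pair[1]}"] = comp.dunn_p[pair]
            row[f"sig {pair[0]} vs {pair[1]}"] = sig
        rows.append(row)
    return pd.DataFrame(rows)
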