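"""Statistical reporting conventions for hierarchical imaging data.

The unit of analysis is the independent experiment, not the cell or track
("superplot" convention): per-condition values are first condensed to one
mean per (condition, experiment), and all tests run on those means.
Provided tests mirror the conventions of quantitative autophagy imaging
papers: one-way ANOVA with Dunnett's many-to-one comparisons against a
control, one-sample t-tests on normalized values, and nonparametric
alternatives (Mann-Whitney, Kruskal-Wallis with Dunn's post hoc).  A
normality screen is reported but never used to switch tests automatically.

Also includes the ratiometric mKeima flux statistic: the ratio of median
fluorescence excited at 561 nm (acidic/lysosomal form) over 407 nm
(neutral/cytosolic form), computed on pre-gated event tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "per_experiment_means",
    "anova_dunnett",
    "one_sample_t",
    "keima_ratio",
    "normality_report",
    "mann_whitney",
    "kruskal_dunn",
]

VALUE = "value"
CONDITION = "condition"
EXPERIMENT = "experiment_id"


@dataclass
class GroupStats:
    """One-way ANOVA + Dunnett results on per-experiment means."""

    control: str
    group_means: pd.DataFrame      # condition, n_experiments, mean, sd, sem
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    comparisons: pd.DataFrame      # condition, diff, t, p_unadjusted, p_adjusted
    normalization: str = "none"


def per_experiment_means(table: pd.DataFrame) -> pd.DataFrame:
    """Condense raw per-cell/per-track rows to one mean per
    (condition, experiment); empty experiments are dropped with a warning."""
    for col in (CONDITION, EXPERIMENT, VALUE):
        if col not in table.columns:
            raise ValueError(f"table must have a {col!r} column")
    clean = table.dropna(subset=[VALUE])
    dropped = (table.groupby([CONDITION, EXPERIMENT]).size().index
               .difference(clean.groupby([CONDITION, EXPERIMENT])
                           .size().index))
    for cond, exp in dropped:
        warnings.warn(f"experiment {exp!r} of condition {cond!r} has no "
                      f"values; dropped")
    return (clean.groupby([CONDITION, EXPERIMENT], as_index=False)[VALUE]
            .mean())


def anova_dunnett(condensed: pd.DataFrame, control: str) -> GroupStats:
    """Ordinary one-way ANOVA plus Dunnett's multiple-comparisons test
    against ``control``, on per-experiment means.

    Dunnett's adjusted p-values use the multivariate-t distribution of the
    many-to-one contrasts under equal variances; unadjusted p-values are
    two-sided pooled-variance t-tests.  With a single treatment group the
    adjustment is void and both coincide.
    """
    conditions = list(dict.fromkeys(condensed[CONDITION]))
    if control not in conditions:
        raise ValueError(f"control {control!r} not among {conditions}")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    groups = {c: condensed.loc[condensed[CONDITION] == c, VALUE]
              .to_numpy(dtype=float) for c in conditions}
    for c, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"condition {c!r} has {len(vals)} experiments (<2)")

    f_res = sps.f_oneway(*groups.values())
    n_total = sum(len(v) for v in groups.values())
    df = (len(groups) - 1, n_total - len(groups))

    treatments = [c for c in conditions if c != control]
    # fixed QMC seed: the multivariate-t integration is randomized and the
    # report must be reproducible
    dunnett_res = sps.dunnett(*[groups[c] for c in treatments],
                              control=groups[control],
                              rng=np.random.default_rng(0))
    rows = []
    for i, cond in enumerate(treatments):
        t_unadj, p_unadj = sps.ttest_ind(groups[cond], groups[control])
        rows.append({
            CONDITION: cond,
            "diff": float(groups[cond].mean() - groups[control].mean()),
            "t": float(dunnett_res.statistic[i]),
            "p_unadjusted": float(p_unadj),
            "p_adjusted": float(
                np.clip(dunnett_res.pvalue[i], p_unadj, 1.0)),
        })

    means = pd.DataFrame([{
        CONDITION: c,
        "n_experiments": len(v),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "sem": float(v.std(ddof=1) / np.sqrt(len(v))),
    } for c, v in groups.items()])
    return GroupStats(control=control, group_means=means,
                      anova_f=float(f_res.statistic), anova_df=df,
                      anova_p=float(f_res.pvalue),
                      comparisons=pd.DataFrame(rows))


def one_sample_t(values, mu: float = 1.0) -> tuple[float, float]:
    """Two-sided one-sample t-test against a normalization reference."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    if np.ptp(vals) == 0:
        warnings.warn("zero variance: one-sample t-test p undefined")
        return float("nan"), float("nan")
    res = sps.ttest_1samp(vals, mu)
    return float(res.statistic), float(res.pvalue)


def keima_ratio(events: pd.DataFrame, col_561: str = "intensity_561",
                col_407: str = "intensity_407") -> float:
    """mKeima flux statistic: median(561-excited) / median(407-excited)
    over a sample's (pre-gated) events."""
    if len(events) == 0:
        raise ValueError("no events")
    m561 = float(np.median(events[col_561]))
    m407 = float(np.median(events[col_407]))
    if m407 <= 0:
        raise ValueError(f"non-positive 407-nm median ({m407}); "
                         f"ratio undefined")
    return m561 / m407


# ---------------------------------------------------------------------------
# screening and nonparametric alternatives
# ---------------------------------------------------------------------------

def normality_report(condensed: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk, D'Agostino and Kolmogorov-Smirnov screens per
    condition (report only — no automatic test switching)."""
    rows = []
    for cond, grp in condensed.groupby(CONDITION):
        v = grp[VALUE].to_numpy(dtype=float)
        row = {CONDITION: cond, "n": len(v)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["shapiro_p"] = (float(sps.shapiro(v).pvalue)
                                if 3 <= len(v) < 5000 else np.nan)
            row["dagostino_p"] = (float(sps.normaltest(v).pvalue)
                                  if len(v) >= 8 else np.nan)
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            row["ks_p"] = (float(sps.kstest(
                v, "norm", args=(v.mean(), sd)).pvalue)
                if sd > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test."""
    res = sps.mannwhitneyu(np.asarray(a, float), np.asarray(b, float),
                           alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(condensed: pd.DataFrame, control: str,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Kruskal-Wallis followed by Dunn's many-to-one z-tests against the
    control, with tie correction and Bonferroni (or Sidak) adjustment."""
    conditions = list(dict.fromkeys(condensed[CONDITION]))
    if control not in conditions:
        raise ValueError(f"control {control!r} not among {conditions}")
    groups = {c: condensed.loc[condensed[CONDITION] == c, VALUE]
              .to_numpy(dtype=float) for c in conditions}
    kw_stat, kw_p = sps.kruskal(*groups.values())

    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / (12.0 * (n_total - 1)) if n_total > 1 else 0.0)
    mean_ranks, sizes, pos = {}, {}, 0
    for c, v in groups.items():
        mean_ranks[c] = ranks[pos:pos + len(v)].mean()
        sizes[c] = len(v)
        pos += len(v)

    m = len(conditions) - 1
    rows = []
    for cond in conditions:
        if cond == control:
            continue
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[cond] + 1.0 / sizes[control]))
        z = (mean_ranks[cond] - mean_ranks[control]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(p * m, 1.0)
        elif adjust == "sidak":
            p_adj = 1.0 - (1.0 - p) ** m
        else:
            raise ValueError("adjust must be 'bonferroni' or 'sidak'")
        rows.append({CONDITION: cond, "z": float(z),
                     "p_unadjusted": float(p), "p_adjusted": float(p_adj),
                     "kruskal_h": float(kw_stat),
                     "kruskal_p": float(kw_p)})
    return pd.DataFrame(rows)
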