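"""Replicate-aware statistics: control normalization, SuperPlot
summaries, the hypothesis tests used for per-field measurements, and the
co-immunoprecipitation interactor filter.

Measurements arrive as long-format tables with columns ``condition``,
``replicate``, (optionally ``field``) and ``value``.  SuperPlot summaries
separate biological-replicate means from individual measurements so that
pseudoreplication is visible; tests can run either on individual data
points or on replicate means.

Post-hoc comparisons are always against a designated control group:
Dunn's rank-based z-tests (Bonferroni-adjusted by default) after
Kruskal-Wallis, or Dunnett's test after one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_table",
    "normalize_counts",
    "superplot_summary",
    "SuperplotSummary",
    "TestReport",
    "run_test",
    "dunn_vs_control",
    "filter_interactors",
]

REQUIRED_COLUMNS = ("condition", "replicate", "value")

DESIGNS = ("ttest", "mannwhitney", "kw_dunn", "anova_dunnett")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    if len(table) == 0:
        raise ValueError("table is empty")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    return table


def normalize_counts(
    table: pd.DataFrame, control_condition: str, scope: str = "per-replicate"
) -> pd.DataFrame:
    """Divide values by the mean control value within each scope.

    ``scope="per-replicate"`` divides each row by the control-condition
    mean of its own replicate (the default: figures pool replicates after
    normalization); ``scope="global"`` uses one overall control mean.  The
    control condition maps to mean 1, making the operation idempotent.
    """
    validate_table(table)
    if scope not in ("per-replicate", "global"):
        raise ValueError(f"scope must be 'per-replicate' or 'global', got {scope!r}")
    ctrl = table[table["condition"] == control_condition]
    if len(ctrl) == 0:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    out = table.copy()
    if scope == "global":
        mean = float(ctrl["value"].mean())
        if mean == 0:
            raise ZeroDivisionError("control mean is 0")
        out["value"] = out["value"] / mean
        return out
    means = ctrl.groupby("replicate")["value"].mean()
    missing = set(out["replicate"]) - set(means.index)
    if missing:
        raise ValueError(f"replicates without control measurements: {sorted(missing)}")
    if (means == 0).any():
        raise ZeroDivisionError("a replicate control mean is 0")
    out["value"] = out["value"] / out["replicate"].map(means).to_numpy()
    return out


class SuperplotSummary(NamedTuple):
    replicate_means: pd.DataFrame  # condition, replicate, mean, n
    condition_summary: pd.DataFrame  # condition, mean_of_replicate_means, pooled_mean, ...


def superplot_summary(table: pd.DataFrame) -> SuperplotSummary:
    """Per-replicate means plus both condition-level summaries.

    Reports, per condition, the mean of replicate means (the
    pseudoreplication-safe summary) alongside the pooled mean over all
    individual points; the two coincide on balanced designs.
    """
    validate_table(table)
    rep = (
        table.groupby(["condition", "replicate"])["value"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    cond = (
        rep.groupby("condition")
        .agg(mean_of_replicate_means=("mean", "mean"), n_replicates=("replicate", "size"))
        .reset_index()
    )
    pooled = table.groupby("condition")["value"].agg(pooled_mean="mean", n_points="size").reset_index()
    cond = cond.merge(pooled, on="condition")
    return SuperplotSummary(rep, cond)


@dataclass
class TestReport:
    """Result of one test design: omnibus statistic plus per-comparison p."""

    design: str
    unit: str
    comparisons: pd.DataFrame  # group, control, statistic, p_raw, p_adj
    omnibus_statistic: float | None = None
    omnibus_p: float | None = None

    @property
    def min_adjusted_p(self) -> float:
        return float(self.comparisons["p_adj"].min())

    def summary(self) -> str:
        lines = [f"design: {self.design}  (unit: {self.unit})"]
        if self.omnibus_p is not None:
            lines.append(
                f"omnibus: statistic = {self.omnibus_statistic:.4g}, p = {self.omnibus_p:.4g}"
            )
        lines.append(self.comparisons.to_string(index=False))
        return "\n".join(lines)


def dunn_vs_control(
    groups: dict[str, np.ndarray], control: str, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z-tests of each group against a control.

    Uses the pooled ranks of all observations with the standard tie
    correction; two-sided normal p-values are adjusted for the number of
    comparisons (Bonferroni by default, any statsmodels method name
    accepted, "none" disables adjustment).
    """
    labels = list(groups)
    if control not in labels:
        raise ValueError(f"control group {control!r} not among {labels}")
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    rank_by_group: dict[str, np.ndarray] = {}
    start = 0
    for g in labels:
        size = groups[g].size
        rank_by_group[g] = ranks[start : start + size]
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var0 = n_total * (n_total + 1) / 12.0 - tie_term
    rc = rank_by_group[control].mean()
    nc = groups[control].size
    rows = []
    for g in labels:
        if g == control:
            continue
        ng = groups[g].size
        se = np.sqrt(var0 * (1.0 / ng + 1.0 / nc))
        z = (rank_by_group[g].mean() - rc) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((g, control, float(z), float(p)))
    out = pd.DataFrame(rows, columns=["group", "control", "statistic", "p_raw"])
    if adjust == "none" or len(out) == 0:
        out["p_adj"] = out["p_raw"]
    else:
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method=adjust)[1]
    return out


def _collapse_to_replicate_means(table: pd.DataFrame) -> pd.DataFrame:
    rep = superplot_summary(table).replicate_means
    return rep.rename(columns={"mean": "value"})[["condition", "replicate", "value"]]


def run_test(
    table: pd.DataFrame,
    design: str,
    unit: str = "points",
    control: str | None = None,
    welch: bool = True,
    dunn_adjust: str = "bonferroni",
) -> TestReport:
    """Run one of the figure-legend test designs on a measurement table.

    Parameters
    ----------
    design : {"ttest", "mannwhitney", "kw_dunn", "anova_dunnett"}
        Two-sample t-test (Welch by default), Mann-Whitney U,
        Kruskal-Wallis with Dunn's post-tests, or one-way ANOVA with
        Dunnett's post-tests.  Post-tests compare every group against the
        ``control`` group.
    unit : {"points", "replicate-means"}
        Test individual data points, or collapse to per-replicate means
        first (the distribution-of-replicate-means comparison).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    if unit not in ("points", "replicate-means"):
        raise ValueError(f"unit must be 'points' or 'replicate-means', got {unit!r}")
    validate_table(table)
    data = _collapse_to_replicate_means(table) if unit == "replicate-means" else table
    labels = list(pd.unique(data["condition"]))
    groups = {g: data.loc[data["condition"] == g, "value"].to_numpy(dtype=float) for g in labels}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if control is None:
        control = labels[0]
    if control not in labels:
        raise ValueError(f"control group {control!r} not among {labels}")
    parametric = design in ("ttest", "anova_dunnett")
    if parametric and any(v.size < 2 for v in groups.values()):
        raise ValueError("parametric designs need >= 2 observations per group")

    if design in ("ttest", "mannwhitney"):
        if len(labels) != 2:
            raise ValueError(f"{design} requires exactly 2 groups, got {len(labels)}")
        other = next(g for g in labels if g != control)
        if design == "ttest":
            res = stats.ttest_ind(groups[other], groups[control], equal_var=not welch)
        else:
            res = stats.mannwhitneyu(groups[other], groups[control], alternative="two-sided")
        comp = pd.DataFrame(
            {
                "group": [other],
                "control": [control],
                "statistic": [float(res.statistic)],
                "p_raw": [float(res.pvalue)],
                "p_adj": [float(res.pvalue)],
            }
        )
        return TestReport(design=design, unit=unit, comparisons=comp)

    treatment_labels = [g for g in labels if g != control]
    if design == "kw_dunn":
        omni = stats.kruskal(*[groups[g] for g in labels])
        comp = dunn_vs_control(groups, control, adjust=dunn_adjust)
    else:
        omni = stats.f_oneway(*[groups[g] for g in labels])
        dunnett = stats.dunnett(
            *[groups[g] for g in treatment_labels], control=groups[control]
        )
        comp = pd.DataFrame(
            {
                "group": treatment_labels,
                "control": control,
                "statistic": np.asarray(dunnett.statistic, dtype=float),
                "p_raw": np.asarray(dunnett.pvalue, dtype=float),
                "p_adj": np.asarray(dunnett.pvalue, dtype=float),  # already family-wise
            }
        )
    return TestReport(
        design=design,
        unit=unit,
        comparisons=comp,
        omnibus_statistic=float(omni.statistic),
        omnibus_p=float(omni.pvalue),
    )


def filter_interactors(
    table: pd.DataFrame,
    min_peptides: int = 10,
    min_ratio: float = 2.0,
    required_replicates: int = 2,
) -> list[str]:
    """Co-IP interactor filter on per-replicate peptide counts.

    A protein is retained iff, in at least ``required_replicates``
    replicates, its bait peptide count is >= ``min_peptides`` AND at least
    ``min_ratio`` times the control count (a control count of 0 passes
    whenever the peptide minimum holds).  A replicate in which the protein
    is absent from the table counts as failing.  Raising either threshold
    can only remove proteins (monotone filter).

    ``table`` columns: protein, replicate, peptides_bait, peptides_control.
    """
    needed = {"protein", "replicate", "peptides_bait", "peptides_control"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    counts = table[["peptides_bait", "peptides_control"]].to_numpy(dtype=float)
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("peptide counts must be non-negative integers")
    if table.duplicated(subset=["protein", "replicate"]).any():
        raise ValueError("each protein must appear at most once per replicate")
    ok = (table["peptides_bait"] >= min_peptides) & (
        table["peptides_bait"] >= min_ratio * table["peptides_control"]
    )
    passing = table.loc[ok].groupby("protein")["replicate"].nunique()
    return sorted(passing[passing >= required_replicates].index.tolist())
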