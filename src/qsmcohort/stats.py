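"""Group statistics on cohort tables.

Implements the full analysis applied to per-region susceptibility and volume
measurements in a three-group (HC / MDD / SCZ) design:

* assumption checks (Shapiro-Wilk per group, Levene across groups);
* one-way ANOVA per region, with Benjamini-Hochberg FDR across the 10
  regions within each measure (susceptibility and volume corrected as
  separate families);
* Tukey HSD post hoc pairwise comparisons, gated on the FDR-corrected ANOVA
  q-value, with an optional second BH step across the three pairs;
* a general linear model of standardized susceptibility on group, pooled-
  standardized volume, and their interaction (treatment coding, HC
  reference), FDR across the five non-intercept terms within a region;
* one-way ANCOVA adjusting the group effect for handedness;
* Pearson correlation screens against clinical covariates with pairwise
  deletion of missing values;
* ANOVA reconstruction from printed summary statistics (means, SDs, n),
  algebraically identical to the raw-data decomposition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

GROUP_ORDER = ("HC", "MDD", "SCZ")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class GroupSummary:
    """Per-group mean/SD/n for one region and one measure."""

    region: str
    measure: str
    groups: tuple
    means: tuple
    sds: tuple
    ns: tuple

    def __post_init__(self):
        if not (len(self.groups) == len(self.means) == len(self.sds) == len(self.ns)):
            raise ValueError("groups, means, sds, ns must have equal length")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2")
        if any(s <= 0 for s in self.sds):
            raise ValueError("SDs must be positive")


@dataclass
class AnovaResult:
    region: str
    measure: str
    f: float
    df: tuple
    p_raw: float
    q_fdr: float = np.nan


@dataclass
class PosthocResult:
    region: str
    pair: str
    t: float
    p_tukey: float
    p_fdr: float = np.nan


@dataclass
class GLMResult:
    """OLS fit of standardized susceptibility on group x standardized volume.

    ``terms`` is indexed by term name with columns B, SE, t, p_raw, q_fdr.
    """

    region: str
    terms: pd.DataFrame
    nobs: int
    df_resid: int


@dataclass
class AncovaResult:
    f: float
    df: tuple
    p: float


@dataclass
class AssumptionReport:
    region: str
    measure: str
    shapiro: dict          # group -> (W, p) or None when skipped
    levene: tuple | None   # (statistic, p) or None
    flags: list = dc_field(default_factory=list)


@dataclass
class StatResultSet:
    anova: dict            # measure -> list[AnovaResult]
    posthoc: dict          # (measure, region) -> list[PosthocResult]
    glm: dict              # region -> GLMResult
    assumptions: list


# ---------------------------------------------------------------------------
# core tests


def _group_arrays(values, group_labels):
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise ValueError("values and group_labels must have equal length")
    groups = [g for g in GROUP_ORDER if g in group_labels]
    groups += [g for g in pd.unique(group_labels) if g not in groups]
    return [(g, values[group_labels == g]) for g in groups]


def anova_oneway(values, group_labels, region=None, measure=None) -> AnovaResult:
    """Classic one-way ANOVA: F = MSB/MSW with df (k-1, N-k)."""
    per_group = _group_arrays(values, group_labels)
    for g, x in per_group:
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    k = len(per_group)
    if k < 2:
        raise ValueError("at least 2 groups required")
    ns = np.array([x.size for _, x in per_group], dtype=float)
    means = np.array([x.mean() for _, x in per_group])
    n_total = ns.sum()
    grand = float(ns @ means / n_total)
    ssb = float(ns @ (means - grand) ** 2)
    ssw = float(sum(((x - x.mean()) ** 2).sum() for _, x in per_group))
    df = (k - 1, int(n_total) - k)
    msb = ssb / df[0]
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = msb / (ssw / df[1])
        p = float(sps.f.sf(f, *df))
    return AnovaResult(region, measure, f, df, p)


def anova_from_summary(summary: GroupSummary) -> AnovaResult:
    """One-way ANOVA recomputed from printed per-group means, SDs, and n.

    SSB = sum n_i (m_i - m_bar)^2, SSW = sum (n_i - 1) s_i^2 — an exact
    refactoring of the raw-data decomposition, usable on published tables.
    """
    ns = np.asarray(summary.ns, dtype=float)
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    k = ns.size
    if k < 2:
        raise ValueError("at least 2 groups required")
    n_total = ns.sum()
    if n_total <= k:
        raise ValueError("total N must exceed the number of groups")
    grand = float(ns @ means / n_total)
    ssb = float(ns @ (means - grand) ** 2)
    ssw = float(((ns - 1) * sds ** 2).sum())
    df = (k - 1, int(n_total) - k)
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / df[0]) / (ssw / df[1])
        p = float(sps.f.sf(f, *df))
    return AnovaResult(summary.region, summary.measure, f, df, p)


def summarize(values, group_labels, region=None, measure=None) -> GroupSummary:
    """Exact sample summary (mean, SD with ddof=1, n) per group."""
    per_group = _group_arrays(values, group_labels)
    return GroupSummary(
        region=region, measure=measure,
        groups=tuple(g for g, _ in per_group),
        means=tuple(float(x.mean()) for _, x in per_group),
        sds=tuple(float(x.std(ddof=1)) for _, x in per_group),
        ns=tuple(int(x.size) for _, x in per_group),
    )


def fdr_bh(p_values):
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D array")
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def tukey_hsd(values, group_labels, region=None, fdr_over_pairs=True):
    """Tukey HSD pairwise comparisons using the pooled MSW.

    For each pair, t = (m_a - m_b) / sqrt(MSW (1/n_a + 1/n_b)); the adjusted
    p-value is P(Q >= |t| sqrt(2)) under the studentized range distribution
    with k groups and N - k df. With ``fdr_over_pairs``, a second BH step is
    applied across the pairs (both corrections, switchable).
    """
    per_group = _group_arrays(values, group_labels)
    for g, x in per_group:
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    k = len(per_group)
    n_total = sum(x.size for _, x in per_group)
    df = n_total - k
    msw = sum(((x - x.mean()) ** 2).sum() for _, x in per_group) / df

    results = []
    for (ga, xa), (gb, xb) in itertools.combinations(per_group, 2):
        # report as "later group vs earlier" (e.g. MDD vs HC)
        diff = xb.mean() - xa.mean()
        if msw == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(msw * (1.0 / xa.size + 1.0 / xb.size))
            t = float(diff / se)
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        results.append(PosthocResult(region, f"{gb} vs {ga}", t, min(p, 1.0)))
    if fdr_over_pairs:
        qs = fdr_bh([r.p_tukey for r in results])
        for r, q in zip(results, qs):
            r.p_fdr = float(q)
    else:
        for r in results:
            r.p_fdr = r.p_tukey
    return results


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - x.mean()) / sd


def glm_group_volume(table: pd.DataFrame, region: str, reference="HC") -> GLMResult:
    """GLM: standardized susceptibility ~ group * standardized volume.

    Both variables are z-scored over the pooled sample (they carry different
    units). Treatment coding with the reference group; BH-FDR across the five
    non-intercept terms.
    """
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValueError(f"region {region!r} not present in table")
    groups = list(pd.unique(sub["group"]))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent for region {region!r}")
    others = [g for g in GROUP_ORDER if g in groups and g != reference]
    others += [g for g in groups if g not in GROUP_ORDER and g != reference]

    y = _zscore(sub["susceptibility_ppm"].to_numpy())
    vol_z = _zscore(sub["volume_mm3"].to_numpy())

    columns = {"Intercept": np.ones(len(sub))}
    for g in others:
        columns[f"group[{g}]"] = (sub["group"] == g).to_numpy(dtype=float)
    columns["volume_z"] = vol_z
    for g in others:
        columns[f"group[{g}]:volume_z"] = columns[f"group[{g}]"] * vol_z
    X = pd.DataFrame(columns, index=sub.index)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design matrix for region {region!r} is rank deficient")
    fit = sm.OLS(y, X).fit()

    terms = pd.DataFrame({
        "B": fit.params, "SE": fit.bse, "t": fit.tvalues, "p_raw": fit.pvalues,
    })
    terms["q_fdr"] = np.nan
    non_intercept = [t for t in terms.index if t != "Intercept"]
    terms.loc[non_intercept, "q_fdr"] = fdr_bh(terms.loc[non_intercept, "p_raw"].to_numpy())
    return GLMResult(region, terms, int(fit.nobs), int(fit.df_resid))


def ancova_handedness(values, group_labels, handedness) -> AncovaResult:
    """One-way ANCOVA: partial F-test of the group factor adjusting for
    handedness (categorical: right / mixed / left; absent levels dropped)."""
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "group": np.asarray(group_labels),
        "hand": np.asarray(handedness),
    }).dropna()
    levels = [h for h in ("right", "mixed", "left") if h in set(df["hand"])]
    absent = [h for h in ("right", "mixed", "left") if h not in levels]
    if absent:
        logger.info("handedness categories absent, dummies dropped: %s", absent)
    groups = [g for g in pd.unique(df["group"])]
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")

    hand_dummies = [(df["hand"] == h).to_numpy(dtype=float) for h in levels[1:]]
    group_dummies = [(df["group"] == g).to_numpy(dtype=float) for g in groups[1:]]
    const = [np.ones(len(df))]

    def rss(cols):
        X = np.column_stack(cols)
        fit = sm.OLS(df["y"].to_numpy(), X).fit()
        return float(fit.ssr), int(fit.df_resid)

    rss_full, df_full = rss(const + group_dummies + hand_dummies)
    rss_red, _ = rss(const + hand_dummies)
    df_group = len(group_dummies)
    if rss_full == 0:
        return AncovaResult(0.0, (df_group, df_full), 1.0)
    f = ((rss_red - rss_full) / df_group) / (rss_full / df_full)
    p = float(sps.f.sf(f, df_group, df_full))
    return AncovaResult(float(f), (df_group, df_full), p)


def correlation_screen(table: pd.DataFrame, region: str, clinical_vars: Sequence[str],
                       group=None) -> pd.DataFrame:
    """Pearson r of susceptibility against clinical variables, with two-sided
    p via the t transform; missing values pairwise-deleted per variable."""
    sub = table[table["region"] == region]
    if group is not None:
        sub = sub[sub["group"] == group]
    rows = []
    for var in clinical_vars:
        pair = sub[["susceptibility_ppm", var]].dropna()
        flag = ""
        r = p = np.nan
        if len(pair) < 3:
            flag = "insufficient_pairs"
        elif pair["susceptibility_ppm"].std() == 0 or pair[var].std() == 0:
            flag = "zero_variance"
        else:
            r, p = sps.pearsonr(pair["susceptibility_ppm"], pair[var])
        rows.append({"variable": var, "n": len(pair), "r": r, "p": p, "flag": flag})
    return pd.DataFrame(rows)


def check_assumptions(table: pd.DataFrame, region: str,
                      measure="susceptibility_ppm") -> AssumptionReport:
    """Shapiro-Wilk per group and Levene (center = mean) across groups.

    Purely reported — results never gate the main analyses.
    """
    sub = table[table["region"] == region]
    flags = []
    shapiro = {}
    samples = []
    for g in pd.unique(sub["group"]):
        x = sub.loc[sub["group"] == g, measure].dropna().to_numpy()
        samples.append(x)
        if x.size < 3:
            shapiro[g] = None
            flags.append(f"shapiro_skipped_{g}_n<3")
        elif np.ptp(x) == 0:
            shapiro[g] = None
            flags.append(f"degenerate_constant_{g}")
        else:
            w, p = sps.shapiro(x)
            shapiro[g] = (float(w), float(p))
    try:
        stat, p = sps.levene(*samples, center="mean")
        levene = (float(stat), float(p))
        if not np.isfinite(stat):
            levene = None
            flags.append("levene_degenerate")
    except Exception:
        levene = None
        flags.append("levene_failed")
    return AssumptionReport(region, measure, shapiro, levene, flags)


# ---------------------------------------------------------------------------
# whole-cohort orchestration and table rendering


def run_anova_family(table: pd.DataFrame, measure: str, regions=None):
    """Per-region one-way ANOVA with BH-FDR across the regions (one family
    per measure)."""
    regions = list(regions) if regions is not None else list(pd.unique(table["region"]))
    results = []
    for region in regions:
        sub = table[table["region"] == region]
        results.append(anova_oneway(sub[measure].to_numpy(),
                                    sub["group"].to_numpy(), region, measure))
    qs = fdr_bh([r.p_raw for r in results])
    for r, q in zip(results, qs):
        r.q_fdr = float(q)
    return results


def analyze_cohort(table: pd.DataFrame, gate=0.05, fdr_over_pairs=True,
                   glm_reference="HC") -> StatResultSet:
    """Full analysis: ANOVA + FDR per measure, gated Tukey post hocs,
    per-region GLM, assumption checks."""
    regions = list(pd.unique(table["region"]))
    anova = {}
    posthoc = {}
    for measure in ("susceptibility_ppm", "volume_mm3"):
        results = run_anova_family(table, measure, regions)
        anova[measure] = results
        for r in results:
            if r.q_fdr < gate:
                sub = table[table["region"] == r.region]
                posthoc[(measure, r.region)] = tukey_hsd(
                    sub[measure].to_numpy(), sub["group"].to_numpy(),
                    r.region, fdr_over_pairs)
            else:
                logger.info("post hoc gate not met for %s / %s (q=%.3g)",
                            measure, r.region, r.q_fdr)

    glm = {}
    for region in regions:
        try:
            glm[region] = glm_group_volume(table, region, glm_reference)
        except ValueError as exc:
            logger.warning("GLM skipped for region %s: %s", region, exc)

    assumptions = [check_assumptions(table, region, m)
                   for region in regions
                   for m in ("susceptibility_ppm", "volume_mm3")]
    return StatResultSet(anova, posthoc, glm, assumptions)


def _sig(x, digits=3):
    """Format to 2-3 significant figures like a published table."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if x == 0:
        return "0"
    return f"{float(f'%.{digits - 1}e' % x):g}"


def build_tables(results: StatResultSet, table: pd.DataFrame):
    """Render per-measure report tables (mean (SD) per group, F, p, q, post
    hoc column populated only where the gate was met).

    Returns {measure: DataFrame} plus {measure: markdown string}.
    """
    frames = {}
    markdown = {}
    groups = [g for g in GROUP_ORDER if g in set(table["group"])]
    for measure, anovas in results.anova.items():
        rows = []
        for a in anovas:
            sub = table[table["region"] == a.region]
            row = {"region": a.region}
            for g in groups:
                x = sub.loc[sub["group"] == g, measure]
                if x.empty:
                    row[g] = ""
                    logger.warning("missing cell: %s / %s / %s", measure, a.region, g)
                else:
                    row[g] = f"{_sig(x.mean())} ({_sig(x.std(ddof=1), 2)})"
            row["F"] = _sig(a.f)
            row["p"] = _sig(a.p_raw, 2)
            row["q"] = _sig(a.q_fdr, 2)
            ph = results.posthoc.get((measure, a.region))
            row["post_hoc"] = "; ".join(
                f"{r.pair}: p={_sig(r.p_fdr, 2)}" for r in ph) if ph else ""
            rows.append(row)
        df = pd.DataFrame(rows)
        frames[measure] = df
        markdown[measure] = df.to_markdown(index=False)
    return frames, markdown


def reproduce_anova(summary_table: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-region ANOVA F/p from a printed-summary CSV
    (columns: region, measure, group, mean, sd, n), with BH-FDR per measure."""
    required = {"region", "measure", "group", "mean", "sd", "n"}
    missing = required - set(summary_table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    rows = []
    for (measure, region), grp in summary_table.groupby(["measure", "region"],
                                                        sort=False):
        gs = GroupSummary(region, measure, tuple(grp["group"]),
                          tuple(grp["mean"]), tuple(grp["sd"]),
                          tuple(int(n) for n in grp["n"]))
        res = anova_from_summary(gs)
        rows.append({"region": region, "measure": measure, "F": res.f,
                     "df1": res.df[0], "df2": res.df[1], "p": res.p_raw})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for measure in pd.unique(out["measure"]):
        sel = out["measure"] == measure
        out.loc[sel, "q"] = fdr_bh(out.loc[sel, "p"].to_numpy())
    return out
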