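"""Renin-angiotensin and L-Arg/ADMA endpoint statistics.

Computes the derived per-animal ratios (Ang-(1-7)/Ang II for the
protective-vs-detrimental angiotensin balance, L-Arg/ADMA as a proxy of NO
bioavailability), group percent changes, omnibus group comparisons
(Kruskal-Wallis with Dunn-Holm post hoc, or one-way ANOVA with Tukey HSD
and Kolmogorov-Smirnov normality checks), rank correlations, and the
joined function-biochemistry cohort profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RATIO_DEFINITIONS",
    "CorrelationResult",
    "GroupTestResult",
    "CohortProfile",
    "derive_ratios",
    "group_percent_change",
    "compare_groups",
    "correlate",
    "profile_cohort",
]

# ratio name -> (numerator analyte, denominator analyte)
RATIO_DEFINITIONS: Dict[str, Tuple[str, str]] = {
    "Ang-(1-7)/Ang II": ("Ang-(1-7)", "Ang II"),
    "L-Arg/ADMA": ("L-Arg", "ADMA"),
}


def derive_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """Append per-animal Ang-(1-7)/Ang II and L-Arg/ADMA ratio records.

    Ratios are dimensionless (``units='ratio'``).  A zero denominator makes
    that animal's ratio undefined (NaN, ``flag='zero denominator'``) rather
    than infinite; a missing numerator or denominator analyte raises an
    error naming the animal and analyte.
    """
    required = {"animal_id", "group", "analyte", "concentration", "units"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    out = panel.copy()
    if "flag" not in out.columns:
        out["flag"] = ""
    wide = panel.pivot_table(
        index=["animal_id", "group"],
        columns="analyte",
        values="concentration",
        aggfunc="first",
    )
    new_rows = []
    for name, (num, den) in RATIO_DEFINITIONS.items():
        for analyte in (num, den):
            if analyte not in wide.columns:
                raise ValueError(f"analyte {analyte!r} missing from the panel")
            bad = wide.index[wide[analyte].isna()]
            if len(bad):
                aid = bad[0][0]
                raise ValueError(f"animal {aid!r} is missing analyte {analyte!r}")
        for (aid, grp), row in wide.iterrows():
            den_v = row[den]
            if den_v == 0:
                new_rows.append((aid, grp, name, np.nan, "ratio", "zero denominator"))
            else:
                new_rows.append((aid, grp, name, row[num] / den_v, "ratio", ""))
    ratios = pd.DataFrame(
        new_rows,
        columns=["animal_id", "group", "analyte", "concentration", "units", "flag"],
    )
    return pd.concat([out, ratios], ignore_index=True)


def _group_location(values: np.ndarray, location: str) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("group has no defined values")
    if location == "mean":
        return float(np.mean(values))
    if location == "median":
        return float(np.median(values))
    raise ValueError(f"unknown location {location!r}")


def group_percent_change(
    panel: pd.DataFrame,
    analyte: str,
    reference_group: str,
    treated_group: str,
    location: str = "mean",
) -> float:
    """Percent change of a group location: 100 x (treated - ref) / ref."""
    sub = panel[panel["analyte"] == analyte]
    ref = sub.loc[sub["group"] == reference_group, "concentration"].to_numpy()
    trt = sub.loc[sub["group"] == treated_group, "concentration"].to_numpy()
    if ref.size == 0 or trt.size == 0:
        raise ValueError(
            f"empty group for analyte {analyte!r}: "
            f"ref n={ref.size}, treated n={trt.size}"
        )
    loc_ref = _group_location(ref, location)
    loc_trt = _group_location(trt, location)
    if loc_ref == 0:
        raise ValueError("reference location is zero: percent change undefined")
    return 100.0 * (loc_trt - loc_ref) / loc_ref


@dataclass
class GroupTestResult:
    """Omnibus group comparison with post-hoc table and normality record."""

    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame
    normality: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value must lie in (0, 1]")


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum z-tests for all pairs, Holm-adjusted.

    Uses the pooled average ranks (average ranks for ties) and the
    tie-corrected variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((f"{a} vs {b}", z, p))
    table = pd.DataFrame(rows, columns=["comparison", "statistic", "p_value"])
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="holm")[1]
    else:
        table["p_adjusted"] = []
    return table


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "nonparametric",
) -> GroupTestResult:
    """Omnibus comparison of >= 2 groups.

    ``design='nonparametric'`` runs Kruskal-Wallis (tie-corrected H) with
    Dunn's post-hoc z-tests and Holm adjustment; ``'parametric'`` runs
    one-way ANOVA with Tukey's HSD.  A per-group Kolmogorov-Smirnov
    normality check (against a normal with the sample mean and SD) is
    recorded either way.  Post-hoc tables are produced only for >= 3
    groups.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n={v.size} < 2")

    norm_rows = []
    for g, v in groups.items():
        sd = v.std(ddof=1)
        if sd > 0:
            ks_stat, ks_p = stats.kstest(v, "norm", args=(v.mean(), sd))
        else:
            ks_stat, ks_p = 0.0, 1.0
        norm_rows.append((g, ks_stat, ks_p))
    normality = pd.DataFrame(norm_rows, columns=["group", "statistic", "p_value"])

    samples = list(groups.values())
    if design == "nonparametric":
        if np.ptp(np.concatenate(samples)) == 0:
            statistic, p = 0.0, 1.0  # all values identical: no evidence
        else:
            statistic, p = stats.kruskal(*samples)
        name = "Kruskal-Wallis"
        posthoc = (
            _dunn_posthoc(groups) if len(groups) >= 3 else pd.DataFrame(
                columns=["comparison", "statistic", "p_value", "p_adjusted"]
            )
        )
    elif design == "parametric":
        statistic, p = stats.f_oneway(*samples)
        if np.isnan(statistic):  # zero variance everywhere
            statistic, p = 0.0, 1.0
        name = "one-way ANOVA"
        if len(groups) >= 3:
            hsd = stats.tukey_hsd(*samples)
            names = list(groups)
            rows = []
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    rows.append(
                        (
                            f"{names[i]} vs {names[j]}",
                            hsd.statistic[i, j],
                            hsd.pvalue[i, j],
                            hsd.pvalue[i, j],
                        )
                    )
            posthoc = pd.DataFrame(
                rows, columns=["comparison", "statistic", "p_value", "p_adjusted"]
            )
        else:
            posthoc = pd.DataFrame(
                columns=["comparison", "statistic", "p_value", "p_adjusted"]
            )
    else:
        raise ValueError(f"unknown design {design!r}")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return GroupTestResult(name, float(statistic), p, posthoc, normality)


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two per-animal readouts."""

    method: str
    r: float
    p_value: float
    n: int
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman is computed as Pearson on average ranks (ties averaged).
    Pairs with a missing value are dropped; constant vectors make the
    correlation undefined and raise an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError(f"need n >= 3 paired values, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    elif method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return CorrelationResult(method, float(r), p, int(xa.size), x_label, y_label)


@dataclass
class CohortProfile:
    """Joined function-biochemistry cohort report."""

    per_animal: pd.DataFrame
    group_summary: pd.DataFrame
    correlations: List[CorrelationResult]
    percent_change: pd.DataFrame

    def correlation(self, x_label: str, y_label: str) -> CorrelationResult:
        for c in self.correlations:
            if {c.x_label, c.y_label} == {x_label, y_label}:
                return c
        raise KeyError(f"no correlation for pair ({x_label!r}, {y_label!r})")


# endpoint -> location estimator used for group summaries / percent change:
# mean +/- SEM for concentrations and ratios, median for the count-like and
# non-parametric imaging endpoints.
_ENDPOINT_LOCATION = {
    "bca_volume_change_pct": "median",
    "npx50": "median",
    "L-Arg/ADMA": "mean",
    "Ang-(1-7)/Ang II": "mean",
}


def profile_cohort(
    imaging: pd.DataFrame,
    panel: pd.DataFrame,
    reference_group: Optional[str] = None,
    method: str = "spearman",
) -> CohortProfile:
    """Join per-animal imaging endpoints with the plasma panel and profile.

    Reproduces the published pairing structure: {BCA volume change, Npx50}
    crossed with {L-Arg/ADMA, Ang-(1-7)/Ang II}, plus volume change x Npx50
    itself; emits per-group summaries and percent-change tables against the
    reference (untreated) group.  Output is invariant to row order.
    """
    req = {"animal_id", "group", "bca_volume_change_pct", "npx50"}
    if not req.issubset(imaging.columns):
        raise ValueError(f"imaging table must have columns {sorted(req)}")
    ratios = derive_ratios(panel)
    wide = ratios[ratios["analyte"].isin(RATIO_DEFINITIONS)].pivot_table(
        index=["animal_id", "group"],
        columns="analyte",
        values="concentration",
        aggfunc="first",
    ).reset_index()
    img = imaging.sort_values("animal_id").reset_index(drop=True)
    orphan_img = sorted(set(img["animal_id"]) - set(wide["animal_id"]))
    orphan_pan = sorted(set(wide["animal_id"]) - set(img["animal_id"]))
    if orphan_img or orphan_pan:
        raise ValueError(
            "animal_id mismatch between imaging and panel; "
            f"imaging-only: {orphan_img}, panel-only: {orphan_pan}"
        )
    merged = img.merge(wide.drop(columns="group"), on="animal_id").sort_values(
        "animal_id"
    )

    pairs = [
        ("bca_volume_change_pct", "npx50"),
        ("bca_volume_change_pct", "L-Arg/ADMA"),
        ("bca_volume_change_pct", "Ang-(1-7)/Ang II"),
        ("npx50", "L-Arg/ADMA"),
        ("npx50", "Ang-(1-7)/Ang II"),
    ]
    correlations = [
        correlate(merged[a], merged[b], method, x_label=a, y_label=b)
        for a, b in pairs
    ]

    endpoints = list(_ENDPOINT_LOCATION)
    summary_rows = []
    for g, sub in merged.groupby("group", sort=True):
        for e in endpoints:
            v = sub[e].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            summary_rows.append(
                (
                    g,
                    e,
                    len(v),
                    float(np.mean(v)),
                    float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                    float(np.median(v)),
                )
            )
    summary = pd.DataFrame(
        summary_rows, columns=["group", "endpoint", "n", "mean", "sem", "median"]
    )

    if reference_group is None:
        untreated = [g for g in merged["group"].unique() if "Untreated" in g]
        reference_group = sorted(untreated)[0] if untreated else None
    pc_rows = []
    if reference_group is not None:
        ref = merged[merged["group"] == reference_group]
        for g in sorted(merged["group"].unique()):
            if g == reference_group:
                continue
            sub = merged[merged["group"] == g]
            for e in endpoints:
                loc = _ENDPOINT_LOCATION[e]
                ref_loc = _group_location(ref[e].to_numpy(dtype=float), loc)
                if ref_loc == 0:
                    continue
                g_loc = _group_location(sub[e].to_numpy(dtype=float), loc)
                pc_rows.append(
                    (g, reference_group, e, loc, 100.0 * (g_loc - ref_loc) / ref_loc)
                )
    percent_change = pd.DataFrame(
        pc_rows,
        columns=["group", "reference_group", "endpoint", "location", "percent_change"],
    )
    return CohortProfile(
        per_animal=merged.reset_index(drop=True),
        group_summary=summary,
        correlations=correlations,
        percent_change=percent_change,
    )
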