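"""Nonparametric group comparison of biosignal features.

The study design compares each feature across pain-intensity classes
(mild / moderate / severe NRS) and pain types (nociceptive / neuropathic /
mixed) with the Kruskal-Wallis rank test (tie-corrected, chi-square
reference distribution), followed by Dunn's pairwise post hoc z-tests on
pooled midranks with both raw and Benjamini-Hochberg-adjusted p-values
(the BH family is the set of pairwise comparisons of one feature under one
grouping).  Normality is screened per group with Shapiro-Wilk for
reporting only; the nonparametric path is always taken.  The same analyses
are repeated within clinical strata (bone metastases, breakthrough cancer
pain, morphine-equivalent dose class).

The Kruskal-Wallis, Dunn and BH steps are implemented here explicitly (they
are the package's statistical contract and are cross-checked against
independent oracles in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

ALPHA = 0.05
DEFAULT_GROUPINGS = ("pain_intensity_class", "pain_type")
DEFAULT_STRATA = ("bone_metastases", "btcp", "med_over_60")

GROUP_ORDER = {
    "pain_intensity_class": ["mild", "moderate", "severe"],
    "pain_type": ["nociceptive", "neuropathic", "mixed"],
}


@dataclass
class PairwiseResult:
    """One Dunn pairwise comparison."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float = float("nan")


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis result for one feature under one grouping."""

    feature: str
    grouping: str
    H: float
    df: int
    p_value: float
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    group_iqrs: dict[str, float]
    shapiro_p: dict[str, float]
    non_normal: bool
    pairwise: list[PairwiseResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Core procedures
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, None, 1.0)
    return adj


def kw_pvalue(h: float, df: int) -> float:
    """Upper-tail chi-square probability for a Kruskal-Wallis statistic.

    Useful for verifying reported statistic/p-value pairs.
    """
    return float(sstats.chi2.sf(h, df))


def _pooled_ranks(groups: Mapping[str, np.ndarray]):
    keys = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in keys]
    sizes = np.array([v.size for v in values])
    if np.any(sizes < 1):
        empty = keys[int(np.argmin(sizes))]
        raise ValueError(f"group {empty!r} is empty")
    pooled = np.concatenate(values)
    n = pooled.size
    ranks = sstats.rankdata(pooled)  # midranks
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {k: float(ranks[bounds[i]:bounds[i + 1]].mean())
                  for i, k in enumerate(keys)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    return keys, sizes, n, mean_ranks, tie_counts


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square upper-tail p.

    Returns ``(H, df, p)`` with ``df = k - 1``.
    """
    keys, sizes, n, mean_ranks, ties = _pooled_ranks(groups)
    k = len(keys)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    if np.any(sizes < 1):
        empty = keys[int(np.argmin(sizes))]
        raise ValueError(f"group {empty!r} is empty")
    if n < k + 1:
        raise ValueError(f"total n={n} too small for k={k} groups")
    tie_div = 1.0 - float(np.sum(ties ** 3 - ties)) / (n ** 3 - n)
    if tie_div == 0.0:
        raise ValueError("all values identical: Kruskal-Wallis statistic undefined")
    h = (12.0 / (n * (n + 1))
         * sum(sizes[i] * mean_ranks[keys[i]] ** 2 for i in range(k))
         - 3.0 * (n + 1)) / tie_div
    df = k - 1
    p = float(sstats.chi2.sf(h, df))
    return float(h), df, p


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> list[PairwiseResult]:
    """Dunn's pairwise z-tests on pooled midranks, two-sided, BH-adjusted.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` with
    the tie term ``T = sum(t^3 - t) / (12 (N - 1))``; the BH family is the
    ``k(k-1)/2`` pairs of this call.
    """
    keys, sizes, n, mean_ranks, ties = _pooled_ranks(groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 1):
        raise ValueError("empty group")
    tie_term = float(np.sum(ties ** 3 - ties)) / (12.0 * (n - 1))
    var_core = n * (n + 1) / 12.0 - tie_term
    if var_core <= 0:
        raise ValueError("all values identical: Dunn variance undefined")
    size_of = dict(zip(keys, sizes))
    results = []
    for a, b in combinations(keys, 2):
        se = np.sqrt(var_core * (1.0 / size_of[a] + 1.0 / size_of[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = float(2.0 * sstats.norm.sf(abs(z)))
        results.append(PairwiseResult(a, b, float(z), min(p, 1.0)))
    adj = bh_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def shapiro_screen(groups: Mapping[str, Sequence[float]],
                   alpha: float = ALPHA) -> tuple[dict[str, float], bool]:
    """Per-group Shapiro-Wilk p-values and a non-normality flag.

    Groups with fewer than 3 values (or degenerate, constant values) get a
    missing p; the flag is decided from the remaining groups.  The flag is
    reporting only — the nonparametric path is taken regardless.
    """
    pvals: dict[str, float] = {}
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            pvals[k] = float("nan")
            continue
        pvals[k] = float(sstats.shapiro(v).pvalue)
    flag = any(p < alpha for p in pvals.values() if not np.isnan(p))
    return pvals, flag


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["feature", "grouping", "stratum_var", "stratum_level",
                  "group_a", "group_b", "n_a", "n_b",
                  "median_a", "iqr_a", "median_b", "iqr_b",
                  "H", "df", "p_kw", "z", "p_raw", "p_adj",
                  "non_normal", "sig_raw", "sig_adj", "computable", "note"]


@dataclass
class ComparisonReport:
    """Tidy per-feature comparison results with per-pair rows.

    Overall (Kruskal-Wallis) rows have empty ``group_a``/``group_b``;
    pairwise (Dunn) rows repeat the omnibus statistics and add z, raw and
    BH-adjusted p.  Comparisons that a stratum makes impossible are kept as
    rows with ``computable=False`` and an explanatory note.
    """

    table: pd.DataFrame
    alpha: float = ALPHA

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def overall(self) -> pd.DataFrame:
        t = self.table
        return t[t["group_a"].isna() & t["computable"]]

    def pairwise(self) -> pd.DataFrame:
        t = self.table
        return t[t["group_a"].notna() & t["computable"]]

    def summary(self, grouping: str, stratum_var=None, stratum_level=None) -> str:
        """Plain-text table of H, p, and flagged pairs for one grouping."""
        t = self.table
        sel = (t["grouping"] == grouping)
        sel &= t["stratum_var"].isna() if stratum_var is None else (
            (t["stratum_var"] == stratum_var) & (t["stratum_level"] == stratum_level))
        lines = [f"Kruskal-Wallis / Dunn results by {grouping}"
                 + ("" if stratum_var is None else f" [{stratum_var}={stratum_level}]"),
                 f"{'feature':<20}{'H':>8}{'df':>4}{'p':>8}  significant pairs (adj p)"]
        for _, row in t[sel & t["group_a"].isna()].iterrows():
            if not row["computable"]:
                lines.append(f"{row['feature']:<20}{'--':>8}{'--':>4}{'--':>8}  {row['note']}")
                continue
            pairs = t[sel & (t["feature"] == row["feature"]) & t["group_a"].notna()]
            sig = [f"{p.group_a}-{p.group_b} ({p.p_adj:.3f})"
                   for p in pairs.itertuples() if p.p_adj < self.alpha]
            lines.append(f"{row['feature']:<20}{row['H']:>8.2f}{int(row['df']):>4}"
                         f"{row['p_kw']:>8.3f}  {'; '.join(sig) if sig else '-'}")
        return "\n".join(lines)


def _groups_from(df: pd.DataFrame, feature: str, grouping: str) -> dict[str, np.ndarray]:
    order = GROUP_ORDER.get(grouping)
    levels = order if order is not None else sorted(df[grouping].dropna().unique())
    out = {}
    for level in levels:
        vals = df.loc[df[grouping] == level, feature].dropna().to_numpy(dtype=float)
        out[str(level)] = vals
    return out


def compare_feature(df: pd.DataFrame, feature: str, grouping: str
                    ) -> GroupComparisonResult:
    """Kruskal-Wallis + Dunn + Shapiro screen for one feature/grouping."""
    groups = _groups_from(df, feature, grouping)
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError(f"grouping {grouping!r} leaves fewer than 2 nonempty groups")
    h, dfree, p = kruskal_wallis(groups)
    pairs = dunn_posthoc(groups)
    shp, flag = shapiro_screen(groups)
    med = {k: float(np.median(v)) for k, v in groups.items()}
    iqr = {k: float(np.percentile(v, 75) - np.percentile(v, 25)) for k, v in groups.items()}
    return GroupComparisonResult(
        feature=feature, grouping=grouping, H=h, df=dfree, p_value=p,
        group_sizes={k: int(v.size) for k, v in groups.items()},
        group_medians=med, group_iqrs=iqr, shapiro_p=shp, non_normal=flag,
        pairwise=pairs)


def run_comparisons(features: pd.DataFrame, cohort: pd.DataFrame,
                    groupings: Sequence[str] = DEFAULT_GROUPINGS,
                    strata: Sequence[str] = DEFAULT_STRATA,
                    feature_columns: Sequence[str] | None = None,
                    alpha: float = ALPHA) -> ComparisonReport:
    """Full comparison report: every feature x grouping, overall and per stratum.

    ``features`` and ``cohort`` must join one-to-one on ``patient_id``.
    Patients with a missing feature value are dropped per feature (pairwise
    deletion).  A stratum that leaves a comparison undefined (an empty
    group, or identical values throughout) yields a ``computable=False``
    row rather than a silent omission.
    """
    if "patient_id" not in features.columns or "patient_id" not in cohort.columns:
        raise ValueError("both tables need a patient_id column")
    orphans = set(features["patient_id"]) ^ set(cohort["patient_id"])
    if orphans:
        raise ValueError(f"patient_id mismatch between tables: {sorted(orphans)[:5]}")
    df = features.merge(cohort, on="patient_id", validate="one_to_one")
    if feature_columns is None:
        feature_columns = [c for c in features.columns if c != "patient_id"]

    rows: list[dict] = []

    def emit(feature, grouping, svar, slevel, sub):
        base = dict(feature=feature, grouping=grouping,
                    stratum_var=svar, stratum_level=slevel)
        try:
            res = compare_feature(sub, feature, grouping)
        except ValueError as exc:
            rows.append({**base, "computable": False, "note": str(exc)})
            return
        rows.append({**base, "H": res.H, "df": res.df, "p_kw": res.p_value,
                     "non_normal": res.non_normal, "computable": True, "note": "",
                     "sig_raw": res.p_value < alpha, "sig_adj": res.p_value < alpha})
        for pr in res.pairwise:
            rows.append({**base, "group_a": pr.group_a, "group_b": pr.group_b,
                         "n_a": res.group_sizes[pr.group_a],
                         "n_b": res.group_sizes[pr.group_b],
                         "median_a": res.group_medians[pr.group_a],
                         "iqr_a": res.group_iqrs[pr.group_a],
                         "median_b": res.group_medians[pr.group_b],
                         "iqr_b": res.group_iqrs[pr.group_b],
                         "H": res.H, "df": res.df, "p_kw": res.p_value,
                         "z": pr.z, "p_raw": pr.p_raw, "p_adj": pr.p_adjusted,
                         "non_normal": res.non_normal,
                         "sig_raw": pr.p_raw < alpha, "sig_adj": pr.p_adjusted < alpha,
                         "computable": True, "note": ""})

    for feature in feature_columns:
        for grouping in groupings:
            emit(feature, grouping, None, None, df)
            for svar in strata:
                for slevel in sorted(df[svar].dropna().unique()):
                    emit(feature, grouping, svar, slevel, df[df[svar] == slevel])

    table = pd.DataFrame(rows).reindex(columns=REPORT_COLUMNS)
    return ComparisonReport(table=table, alpha=alpha)
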