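"""Nonparametric statistics for the fBOS cohort analyses.

Group differences use Kruskal-Wallis with tie correction and post-hoc
pairwise comparisons of mean ranks with a Tukey-Kramer-type critical
range (the behaviour of MATLAB's ``multcompare`` after
``kruskalwallis``); a Dunn-Bonferroni variant is available behind a
flag. Correlations use Spearman's rho (average ranks for ties) and
Kendall's tau-b, appropriate for heavily tied clinical scores. Missing
values are removed per test (listwise per pair/group) and the n actually
used is reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

FBOS_METRICS = ("area_ratio", "norm_length", "norm_width",
                "d_toe", "d_heel", "d_lat_ankle", "d_little_toe")


def _clean(*arrays: np.ndarray) -> List[np.ndarray]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        ok &= np.isfinite(a)
    return [a[ok] for a in arrays]


def kruskal_wallis(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def posthoc_rank(
    groups: Sequence[np.ndarray],
    labels: Optional[Sequence[str]] = None,
    method: str = "tukey_kramer",
) -> Dict[Tuple[str, str], float]:
    """Pairwise family-wise-adjusted p values on group mean ranks.

    ``tukey_kramer`` compares standardised mean-rank differences against
    the studentized range (infinite df), mirroring ``multcompare``;
    ``dunn_bonferroni`` uses normal z tests with Bonferroni adjustment.
    The tie-corrected pooled rank variance N(N+1)/12 · (1 − ΣT/(N³−N)),
    ΣT = Σ(t³−t), is used in both.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n_tot * (n_tot + 1) / 12.0
    if n_tot > 1:
        var *= 1.0 - tie_sum / (n_tot ** 3 - n_tot)

    out: Dict[Tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = abs(mean_ranks[i] - mean_ranks[j])
            if se == 0:
                p = 1.0
            elif method == "tukey_kramer":
                q = diff / se * np.sqrt(2.0)
                p = float(scipy.stats.studentized_range.sf(q, k, np.inf))
            elif method == "dunn_bonferroni":
                z = diff / se
                p = min(1.0, 2.0 * scipy.stats.norm.sf(z) * k * (k - 1) / 2.0)
            else:
                raise ValueError(f"unknown post-hoc method {method!r}")
            out[(labels[i], labels[j])] = p
            out[(labels[j], labels[i])] = p
    return out


def rank_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "spearman"
) -> Tuple[float, float, int]:
    """Spearman rho or Kendall tau-b with two-sided p and the n used.

    Pairs with a missing member are dropped; at least 4 complete pairs
    are required. Ties get average ranks (Spearman) or the tau-b
    correction (Kendall).
    """
    x, y = _clean(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, have {n}")
    if method == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    elif method == "kendall":
        r, p = scipy.stats.kendalltau(x, y)   # tau-b
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), int(n)


def paired_and_unpaired_rank_tests(
    a: np.ndarray, b: np.ndarray, paired: bool
) -> float:
    """Two-sided Wilcoxon p value: signed-rank if paired, rank-sum if not.

    Uses the exact null distribution for small samples without ties and
    the tie/continuity-corrected normal approximation otherwise.
    """
    if paired:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        a, b = _clean(a, b)
        d = a - b
        if np.all(d == 0):
            return 1.0
        res = scipy.stats.wilcoxon(a, b)
        return float(res.pvalue)
    a = np.asarray(a, dtype=float)
    a = a[np.isfinite(a)]
    b = np.asarray(b, dtype=float)
    b = b[np.isfinite(b)]
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


@dataclass
class StatsReport:
    """Reproduction report: medians, group tests and correlations.

    ``group_summary`` has one row per (variable, group) with median, min,
    max and n. ``group_tests`` maps variable → dict with H, p and
    post-hoc pairwise p values. ``correlations`` maps a descriptive name
    to (coefficient, p, n). ``skipped`` lists tests that could not run
    and why.
    """

    group_summary: pd.DataFrame
    group_tests: Dict[str, Dict[str, object]]
    correlations: Dict[str, Tuple[float, float, int]]
    frailty: Dict[str, object]
    sex: Dict[str, float]
    footwear: Dict[str, object]
    skipped: List[str] = field(default_factory=list)


def _groups_of(table: pd.DataFrame, var: str) -> Tuple[List[np.ndarray], List[str]]:
    labels = [g for g in ("young", "middle", "old")
              if (table["group"] == g).any()]
    return ([table.loc[table["group"] == g, var].dropna().to_numpy()
             for g in labels], labels)


def reproduce_paper_statistics(table: pd.DataFrame,
                               posthoc_method: str = "tukey_kramer"
                               ) -> StatsReport:
    """Run the full statistics battery on a cohort table.

    Emits per-group medians/ranges of the fBOS shape variables,
    Kruskal-Wallis + post-hoc across age groups, the Spearman
    correlation of area with age over all participants, Kendall
    correlations of area with SPPB, gait speed, sit-to-stand and FES-I
    in older adults, the frailty-band comparison (levels 1&2 merged vs 3
    vs 4), the standing-length vs walking-COP-path Spearman and the
    walking-path vs stride-speed Kendall in older adults, rank-sum tests
    of area by sex, and the shod-vs-barefoot signed-rank test where both
    conditions exist. Tests whose columns are absent are skipped and
    listed. Deterministic given the table.
    """
    skipped: List[str] = []
    rows = []
    group_tests: Dict[str, Dict[str, object]] = {}
    for var in FBOS_METRICS:
        if var not in table.columns:
            skipped.append(f"group comparison of {var}: column missing")
            continue
        groups, labels = _groups_of(table, var)
        for g, lab in zip(groups, labels):
            if g.size:
                rows.append({"variable": var, "group": lab,
                             "median": float(np.median(g)),
                             "min": float(g.min()), "max": float(g.max()),
                             "n": int(g.size)})
        if len(groups) >= 2 and all(g.size for g in groups):
            h, p = kruskal_wallis(groups)
            group_tests[var] = {
                "H": h, "p": p,
                "posthoc": posthoc_rank(groups, labels, method=posthoc_method),
            }
    summary = pd.DataFrame(rows)

    correlations: Dict[str, Tuple[float, float, int]] = {}

    def corr(name: str, sub: pd.DataFrame, x: str, y: str, method: str) -> None:
        if x not in sub.columns or y not in sub.columns:
            skipped.append(f"{name}: column missing")
            return
        try:
            correlations[name] = rank_correlation(
                sub[x].to_numpy(), sub[y].to_numpy(), method=method)
        except ValueError as exc:
            skipped.append(f"{name}: {exc}")

    corr("spearman_age_area", table, "age", "area_ratio", "spearman")
    old = table[table["group"] == "old"]
    corr("kendall_area_sppb", old, "area_ratio", "sppb", "kendall")
    corr("kendall_area_gait_speed", old, "area_ratio", "gait_speed", "kendall")
    corr("kendall_area_sit_to_stand", old, "area_ratio", "sit_to_stand",
         "kendall")
    corr("kendall_area_fes", old, "area_ratio", "fes_i", "kendall")
    corr("spearman_length_walking_p", old, "norm_length", "walking_p",
         "spearman")
    corr("kendall_walking_p_stride_speed", old, "walking_p", "stride_speed",
         "kendall")

    # frailty bands: levels 1&2 merged, 3, 4
    frailty: Dict[str, object] = {}
    if {"frailty", "area_ratio"}.issubset(old.columns) and old["frailty"].notna().any():
        f = old.dropna(subset=["frailty", "area_ratio"])
        bands = {
            "1&2": f.loc[f["frailty"] <= 2, "area_ratio"].to_numpy(),
            "3": f.loc[f["frailty"] == 3, "area_ratio"].to_numpy(),
            "4": f.loc[f["frailty"] == 4, "area_ratio"].to_numpy(),
        }
        nonempty = {k: v for k, v in bands.items() if v.size}
        frailty["n"] = {k: int(v.size) for k, v in bands.items()}
        if len(nonempty) >= 2:
            h, p = kruskal_wallis(list(nonempty.values()))
            frailty["H"], frailty["p"] = h, p
            med12 = np.median(bands["1&2"]) if bands["1&2"].size else np.nan
            for lvl in ("3", "4"):
                if bands[lvl].size and med12:
                    frailty[f"median_ratio_{lvl}_vs_1&2"] = float(
                        np.median(bands[lvl]) / med12)
            frailty["posthoc"] = posthoc_rank(
                list(nonempty.values()), list(nonempty.keys()),
                method=posthoc_method)
    else:
        skipped.append("frailty comparison: columns missing or empty")

    # rank-sum of area by sex, overall and within young / old
    sex: Dict[str, float] = {}
    if {"sex", "area_ratio"}.issubset(table.columns):
        for name, sub in (("all", table),
                          ("young", table[table["group"] == "young"]),
                          ("old", old)):
            f = sub.loc[sub["sex"] == "F", "area_ratio"].dropna().to_numpy()
            m = sub.loc[sub["sex"] == "M", "area_ratio"].dropna().to_numpy()
            if f.size and m.size:
                sex[name] = paired_and_unpaired_rank_tests(f, m, paired=False)
    else:
        skipped.append("sex comparison: columns missing")

    # shod vs barefoot signed rank, where both conditions exist
    footwear: Dict[str, object] = {}
    if "barefoot_area_ratio" in table.columns:
        both = table.dropna(subset=["area_ratio", "barefoot_area_ratio"])
        footwear["n"] = int(len(both))
        if len(both) >= 2:
            footwear["p_signrank"] = paired_and_unpaired_rank_tests(
                both["area_ratio"].to_numpy(),
                both["barefoot_area_ratio"].to_numpy(), paired=True)
            footwear["median_shod"] = float(both["area_ratio"].median())
            footwear["median_barefoot"] = float(
                both["barefoot_area_ratio"].median())
    else:
        skipped.append("shod vs barefoot: column missing")

    return StatsReport(group_summary=summary, group_tests=group_tests,
                       correlations=correlations, frailty=frailty, sex=sex,
                       footwear=footwear, skipped=skipped)
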