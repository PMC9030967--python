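"""Three-step statistical screening of texture features against EOTRH grade.

For every (feature, filter) series — one value per graded tooth — the screen

1. gates on normality: all four grade groups must pass Shapiro-Wilk;
2. runs an omnibus test at alpha = 0.05: one-way ANOVA on the Gaussian path,
   Kruskal-Wallis (tie-corrected) otherwise, followed by post-hoc pairwise
   comparisons over the six grade pairs: Tukey HSD or Dunn's rank test with
   Bonferroni adjustment;
3. labels the monotone trend: direction is the sign of the Spearman
   correlation between grade and value, and the onset grade is the smallest
   g in {1,2,3} whose pair (0,g) is post-hoc significant with the central
   tendencies from g through grade 3 strictly ordered in that direction.

Two selection criteria summarize each feature across the nine filters:
criterion 1 — some filter shows onset grade 1; criterion 2 — all filters
agree on one non-none trend direction.  The coefficient of variation
(sample SD over |mean|, in percent) is computed on values pooled over all
filters and teeth and compared with its family mean.

No correction is applied across the 837 feature-filter combinations; an
optional Benjamini-Hochberg switch on the omnibus p-values is off by default.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

ALPHA = 0.05


@functools.lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)
GRADE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
MIN_GROUP_N = 3
MAX_SHAPIRO_N = 5000


def normality_gate(groups: list[np.ndarray], alpha: float = ALPHA) -> bool:
    """True iff every grade group passes Shapiro-Wilk at ``alpha``.

    Groups too small to test (n < 3) fail the gate, routing the series to
    the non-parametric path.
    """
    for g, x in enumerate(groups):
        x = np.asarray(x, dtype=np.float64)
        if x.size < MIN_GROUP_N or x.size > MAX_SHAPIRO_N:
            logger.warning("normality gate: group %d has n=%d, using non-parametric path", g, x.size)
            return False
        if np.ptp(x) == 0:  # constant group: certainly not Gaussian
            return False
        if stats.shapiro(x).pvalue < alpha:
            return False
    return True


def omnibus_test(groups: list[np.ndarray], normal: bool) -> float:
    """Omnibus p-value: one-way ANOVA if ``normal`` else Kruskal-Wallis."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        logger.warning("omnibus: all values identical, p = 1 by convention")
        return 1.0
    if normal:
        stat = stats.f_oneway(*groups)
        p = float(stat.pvalue)
        return 1.0 if np.isnan(p) else p
    return float(stats.kruskal(*groups).pvalue)


def _dunn_pairwise(groups: list[np.ndarray], adjust: str = "bonferroni") -> dict[tuple[int, int], float]:
    """Dunn's rank-sum z-tests over all grade pairs, tie-corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p, Bonferroni over the
    six pairs by default.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for x in groups:
        mean_ranks.append(ranks[start : start + len(x)].mean())
        start += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    out = {}
    m = len(GRADE_PAIRS)
    for i, j in GRADE_PAIRS:
        se = np.sqrt(var_factor * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out[(i, j)] = float(p)
    return out


def studentized_range_sf(q: np.ndarray, k: int, df: float) -> np.ndarray:
    """P(Q >= q) for the studentized range of k means with df error dof.

    Evaluates  P(Q <= q) = E_S[ k * int phi(z) (Phi(z) - Phi(z - qS))^(k-1) dz ]
    with S the scaled chi variable sqrt(chi2_df / df), using fixed
    Gauss-Legendre grids.  Agrees with the exact distribution to ~1e-6 for
    the df >= 10 regime the screen operates in.
    """
    q = np.atleast_1d(np.asarray(q, dtype=np.float64))
    # outer grid over s around its concentration point 1 +/- ~10 sd
    sd_s = 1.0 / np.sqrt(2.0 * df)
    s_lo, s_hi = max(1e-9, 1.0 - 10.0 * sd_s), 1.0 + 10.0 * sd_s
    xs, ws = _leggauss(48)
    s = 0.5 * (s_hi - s_lo) * xs + 0.5 * (s_hi + s_lo)
    ws = ws * 0.5 * (s_hi - s_lo)
    log_fs = (
        np.log(2.0)
        + 0.5 * df * np.log(df / 2.0)
        - special.gammaln(df / 2.0)
        + (df - 1.0) * np.log(s)
        - df * s * s / 2.0
    )
    fs = np.exp(log_fs)
    # inner grid over z (phi(z) confines the integrand to |z| <~ 9)
    xz, wz = _leggauss(96)
    z = 9.0 * xz
    wz = 9.0 * wz
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    cdf_z = stats.norm.cdf(z)
    # inner integral for each (q, s): shape (nq, ns, nz)
    qs = q[:, None] * s[None, :]
    inner = cdf_z[None, None, :] - stats.norm.cdf(z[None, None, :] - qs[:, :, None])
    g = k * np.sum(
        (wz * phi)[None, None, :] * np.clip(inner, 0.0, 1.0) ** (k - 1), axis=2
    )
    cdf = np.sum(ws[None, :] * fs[None, :] * g, axis=1)
    return np.clip(1.0 - cdf, 0.0, 1.0)


def _tukey_pairwise(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Tukey-Kramer HSD p-values for all grade pairs (pooled-variance q)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df = int(ns.sum() - k)
    mse = sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)) / df
    qs = []
    for i, j in GRADE_PAIRS:
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        qs.append(abs(means[i] - means[j]) / se if se > 0 else 0.0)
    ps = studentized_range_sf(np.array(qs), k, df)
    return {pair: float(p) for pair, p in zip(GRADE_PAIRS, ps)}


def posthoc_pairwise(
    groups: list[np.ndarray], normal: bool, dunn_adjust: str = "bonferroni"
) -> dict[tuple[int, int], float]:
    """Adjusted p-values for the six grade pairs.

    Tukey HSD (studentized range) on the Gaussian path, Dunn's multiple
    comparisons (Bonferroni-adjusted by default) otherwise.
    """
    if np.ptp(np.concatenate(groups)) == 0:
        return {pair: 1.0 for pair in GRADE_PAIRS}
    if normal:
        return _tukey_pairwise(groups)
    return _dunn_pairwise(groups, adjust=dunn_adjust)


def trend_onset(
    groups: list[np.ndarray],
    pairwise_p: dict[tuple[int, int], float],
    normal: bool,
    omnibus_significant: bool,
    alpha: float = ALPHA,
) -> tuple[str, int | None]:
    """(direction, onset_grade) for a significant series; ("none", None) otherwise.

    Direction is the sign of the Spearman correlation between grade and
    value.  The onset is the smallest grade g whose pair (0, g) is post-hoc
    significant and whose central tendencies (group means on the Gaussian
    path, mean ranks otherwise) are strictly ordered in that direction from
    g through grade 3 — a tie breaks toward the larger onset.
    """
    if not omnibus_significant:
        return "none", None
    grades = np.concatenate([np.full(len(x), g) for g, x in enumerate(groups)])
    values = np.concatenate(groups)
    rho = stats.spearmanr(grades, values).statistic
    if not np.isfinite(rho) or rho == 0:
        return "none", None
    sign = 1.0 if rho > 0 else -1.0
    direction = "increase" if sign > 0 else "decrease"

    if normal:
        tend = np.array([np.mean(x) for x in groups])
    else:
        ranks = stats.rankdata(values)
        tend = np.array(
            [ranks[grades == g].mean() for g in range(len(groups))]
        )

    for g in (1, 2, 3):
        if pairwise_p.get((0, g), 1.0) >= alpha:
            continue
        tail = tend[g:]
        if np.all(sign * np.diff(tail) > 0) or tail.size == 1:
            if sign * (tend[g] - tend[0]) > 0:
                return direction, g
    logger.debug("significant series without a monotone onset: (none, none)")
    return "none", None


def criterion1(onsets: dict[str, int | None]) -> bool:
    """True iff any filter's trend begins at grade 1."""
    return any(v == 1 for v in onsets.values())


def criterion2(directions: dict[str, str]) -> bool:
    """True iff all filters agree on one non-none trend direction."""
    vals = set(directions.values())
    return len(vals) == 1 and vals != {"none"}


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD / |mean| in percent; NaN (with a warning) on zero mean."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        logger.warning("coefficient of variation undefined: zero mean")
        return float("nan")
    return float(values.std(ddof=1) / abs(mean) * 100.0)


@dataclass
class ScreeningResult:
    """Screening grid plus the per-feature selection summary.

    ``screening``: one row per (feature, filter) with the normality flag,
    omnibus p, six pairwise p-values, trend direction and onset grade.
    ``selection``: one row per feature with criterion flags, CV and the
    family-mean CV.  ``family_summary``: per family, the count and percent
    of features passing both criteria and the mean CV.
    ``significant_counts``: family x filter table of significant features.
    """

    screening: pd.DataFrame
    selection: pd.DataFrame
    family_summary: pd.DataFrame
    significant_counts: pd.DataFrame
    n_combinations: int
    n_degenerate: int


def screen_table(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    dunn_adjust: str = "bonferroni",
    fdr: bool = False,
) -> ScreeningResult:
    """Run the full three-step screen on a long-format feature table.

    The table needs columns subject_id, tooth_id, grade, filter, family,
    feature, value (one row per tooth x filter x feature).  Series containing
    NaN (degenerate features) are excluded from testing and counted in
    ``n_degenerate``.  With ``fdr=True`` omnibus p-values are Benjamini-
    Hochberg adjusted across all combinations before thresholding.
    """
    filters = sorted(table["filter"].unique())
    grades_col = table["grade"].to_numpy()
    values_col = table["value"].to_numpy(dtype=np.float64)
    rows = []
    # feature names repeat across families (e.g. gray_level_variance), so a
    # series is keyed by (family, feature, filter)
    for (family, feature, filt), idx in table.groupby(
        ["family", "feature", "filter"], sort=True
    ).indices.items():
        vals = values_col[idx]
        grds = grades_col[idx]
        degenerate = bool(np.isnan(vals).any())
        row = {
            "feature": feature,
            "filter": filt,
            "family": family,
            "degenerate": degenerate,
            "normal": False,
            "omnibus_p": np.nan,
            "significant": False,
            "direction": "none",
            "onset_grade": np.nan,
        }
        for i, j in GRADE_PAIRS:
            row[f"p_{i}{j}"] = np.nan
        if not degenerate:
            groups = [vals[grds == g] for g in range(4)]
            normal = normality_gate(groups, alpha)
            omnibus_p = omnibus_test(groups, normal)
            pairwise = posthoc_pairwise(groups, normal, dunn_adjust)
            row.update(normal=normal, omnibus_p=omnibus_p)
            for (i, j), p in pairwise.items():
                row[f"p_{i}{j}"] = p
            row["_groups"] = groups
            row["_pairwise"] = pairwise
        rows.append(row)

    screening = pd.DataFrame(rows)
    if fdr:
        ok = screening["omnibus_p"].notna()
        screening.loc[ok, "omnibus_p"] = _bh_adjust(
            screening.loc[ok, "omnibus_p"].to_numpy()
        )
    screening["significant"] = screening["omnibus_p"] < alpha

    directions, onsets = [], []
    for _, row in screening.iterrows():
        if row["degenerate"]:
            directions.append("none")
            onsets.append(np.nan)
            continue
        direction, onset = trend_onset(
            row["_groups"], row["_pairwise"], row["normal"],
            bool(row["significant"]), alpha,
        )
        directions.append(direction)
        onsets.append(np.nan if onset is None else onset)
    screening["direction"] = directions
    screening["onset_grade"] = onsets
    screening = screening.drop(columns=["_groups", "_pairwise"], errors="ignore")

    # --- per-feature selection summary -----------------------------------
    pooled_cv = {
        key: coefficient_of_variation(values_col[idx])
        for key, idx in table.groupby(["family", "feature"], sort=True).indices.items()
    }
    sel_rows = []
    for (family, feature), sub in screening.groupby(["family", "feature"], sort=True):
        per_filter_onset = dict(zip(sub["filter"], sub["onset_grade"]))
        per_filter_dir = dict(zip(sub["filter"], sub["direction"]))
        sel_rows.append(
            {
                "feature": feature,
                "family": family,
                "criterion1": criterion1(
                    {f: (None if np.isnan(o) else int(o)) for f, o in per_filter_onset.items()}
                ),
                "criterion2": criterion2(per_filter_dir),
                "cv": pooled_cv[(family, feature)],
            }
        )
    selection = pd.DataFrame(sel_rows)
    fam_mean_cv = selection.groupby("family")["cv"].transform("mean")
    selection["family_mean_cv"] = fam_mean_cv
    selection["above_family_mean_cv"] = selection["cv"] > fam_mean_cv

    fam_rows = []
    for family, sub in selection.groupby("family", sort=True):
        both = sub["criterion1"] & sub["criterion2"]
        fam_rows.append(
            {
                "family": family,
                "n_features": len(sub),
                "n_pass_both": int(both.sum()),
                "pct_pass_both": 100.0 * both.sum() / len(sub),
                "mean_cv": float(sub["cv"].mean()),
            }
        )
    family_summary = pd.DataFrame(fam_rows)

    significant_counts = (
        screening.groupby(["family", "filter"])["significant"]
        .sum()
        .unstack(fill_value=0)
        .astype(int)
    )

    return ScreeningResult(
        screening=screening,
        selection=selection,
        family_summary=family_summary,
        significant_counts=significant_counts,
        n_combinations=len(filters)
        * screening[["family", "feature"]].drop_duplicates().shape[0],
        n_degenerate=int(screening["degenerate"].sum()),
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def family_pass_percentages(
    n_passing: dict[str, int], family_sizes: dict[str, int]
) -> dict[str, float]:
    """Percent of a family's features passing both criteria, to 0.1%."""
    return {
        fam: round(100.0 * n_passing.get(fam, 0) / family_sizes[fam], 1)
        for fam in family_sizes
    }
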