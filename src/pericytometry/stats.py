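"""Group comparison layer: normality screening and rank-based tests.

Per-vessel metric values are compared across experimental groups with
the Kruskal-Wallis omnibus test (tie-corrected), after screening each
group with four normality tests (D'Agostino & Pearson, Anderson-Darling,
Shapiro-Wilk, and the Lilliefors variant of Kolmogorov-Smirnov).  The
normality results are reported for transparency only; they never switch
the test.  Pairwise follow-up uses Dunn's rank comparison with Holm
adjustment -- the standard companion to Kruskal-Wallis, made explicit
here because different software defaults differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupComparison", "compare_groups", "dunn_posthoc"]

NORMALITY_TESTS = (
    "dagostino_pearson",
    "anderson_darling",
    "shapiro_wilk",
    "kolmogorov_smirnov",
)


@dataclass
class GroupComparison:
    """Result of one metric's multi-group comparison."""

    metric_name: str
    groups: dict[str, np.ndarray]
    normality: pd.DataFrame
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.omnibus_p < self.alpha)

    def summary(self) -> str:
        lines = [
            f"metric: {self.metric_name}",
            "  "
            + ", ".join(
                f"{g}: n={len(v)}, median={np.median(v):.4g}"
                for g, v in self.groups.items()
            ),
            f"  Kruskal-Wallis H = {self.omnibus_stat:.4g}, "
            f"p = {self.omnibus_p:.4g}"
            + ("  *" if self.significant else ""),
        ]
        for _, row in self.pairwise.iterrows():
            flag = " *" if row["p_adjusted"] < self.alpha else ""
            lines.append(
                f"  {row['group_a']} vs {row['group_b']}: "
                f"p_adj = {row['p_adjusted']:.4g}{flag}"
            )
        return "\n".join(lines)


def _normality_table(groups: Mapping[str, np.ndarray], alpha: float) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        row: dict = {"group": name, "n": len(vals)}
        constant = np.ptp(vals) == 0
        # D'Agostino & Pearson (requires n >= 8 for the kurtosis moment)
        if len(vals) >= 8 and not constant:
            p = sps.normaltest(vals).pvalue
        else:
            p = np.nan
        row["dagostino_pearson_p"] = p
        # Anderson-Darling
        if not constant:
            try:
                ad = sps.anderson(vals, dist="norm", method="interpolate")
                row["anderson_darling_stat"] = ad.statistic
                row["anderson_darling_pass"] = bool(ad.pvalue > alpha)
            except TypeError:  # older scipy: compare against 5% critical value
                ad = sps.anderson(vals, dist="norm")
                crit = ad.critical_values[list(ad.significance_level).index(5.0)]
                row["anderson_darling_stat"] = ad.statistic
                row["anderson_darling_pass"] = bool(ad.statistic < crit)
            row["shapiro_wilk_p"] = sps.shapiro(vals).pvalue
            # Lilliefors needs n >= 4
            row["kolmogorov_smirnov_p"] = (
                lilliefors(vals, dist="norm")[1] if len(vals) >= 4 else np.nan
            )
        else:
            row["anderson_darling_stat"] = np.nan
            row["anderson_darling_pass"] = False
            row["shapiro_wilk_p"] = np.nan
            row["kolmogorov_smirnov_p"] = np.nan
        for key in ("dagostino_pearson", "shapiro_wilk", "kolmogorov_smirnov"):
            pval = row[f"{key}_p"]
            row[f"{key}_pass"] = bool(pval > alpha) if np.isfinite(pval) else None
        rows.append(row)
    return pd.DataFrame(rows)


def dunn_posthoc(
    groups: Mapping[str, np.ndarray], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12(N - 1)) over tied groups
    of the pooled ranks; two-sided p-values, multiplicity-adjusted.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    ns = [len(groups[g]) for g in names]
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, n in zip(names, ns):
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        denom = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / denom if denom > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method=adjust)[1]
    else:
        df["p_adjusted"] = []
    return df


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric_name: str = "",
    adjust: str = "holm",
) -> GroupComparison:
    """Normality screening + Kruskal-Wallis + Dunn/Holm pairwise.

    Groups with fewer than 3 values are excluded with a warning; fewer
    than 2 usable groups is an error.  Two identical constant groups are
    the degenerate all-ties case: H = 0, p = 1.
    """
    usable: dict[str, np.ndarray] = {}
    for name, vals in samples.items():
        arr = np.asarray([v for v in np.asarray(vals, float) if np.isfinite(v)])
        if len(arr) < 3:
            warnings.warn(
                f"group {name!r} has fewer than 3 values and is excluded",
                stacklevel=2,
            )
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 3 values each")

    normality = _normality_table(usable, alpha)

    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0:
        # all observations tied: no evidence of any difference
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*usable.values())

    pairwise = dunn_posthoc(usable, adjust=adjust)
    return GroupComparison(
        metric_name=metric_name,
        groups=usable,
        normality=normality,
        omnibus_stat=float(H),
        omnibus_p=float(p),
        pairwise=pairwise,
        alpha=alpha,
    )
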