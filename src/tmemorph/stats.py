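"""Univariate statistics: group comparisons, RIS correlations, weights.

Continuous features are compared between outcome groups with the
two-sided Mann–Whitney U test (exact when both groups are small and
untied, tie-corrected normal approximation otherwise); categorical
variables use the Chi-square test, falling back to Fisher's exact test
for 2x2 tables with any expected cell count of 5 or fewer.  Associations with
residual infiltration size (RIS) use Spearman's rank correlation with
midranks for ties — pCR patients contribute RIS = 0, forming a tied
block by design.  Raw p-values are reported at the 0.05 level without
multiplicity correction; reports carry the number of tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

P_SIGNIFICANT = 0.05
_EXACT_MAX_N = 20


@dataclass
class UnivariateResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    rho: float | None = None
    group_medians: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < P_SIGNIFICANT


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    values,
    groups,
    kind: str = "continuous",
    feature: str = "",
) -> UnivariateResult:
    """Two-group univariate comparison of one variable.

    ``kind`` is ``continuous`` (Mann–Whitney U), ``categorical`` or
    ``ordinal`` (Chi-square, or Fisher's exact for sparse 2x2 tables).
    ``groups`` must contain exactly two non-empty groups.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two non-empty groups are required")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")

    if kind == "continuous":
        stat, p = _mann_whitney(a.astype(float), b.astype(float))
        medians = {
            str(levels[0]): float(np.median(a)),
            str(levels[1]): float(np.median(b)),
        }
        return UnivariateResult(feature, "mann_whitney", stat, p,
                                group_medians=medians)
    if kind in ("categorical", "ordinal"):
        table = pd.crosstab(groups, values).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2 or (
            table.sum(axis=0) == 0
        ).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("degenerate contingency table (zero margin)")
        expected = sps.contingency.expected_freq(table)
        if table.shape == (2, 2) and (expected <= 5).any():
            stat, p = sps.fisher_exact(table, alternative="two-sided")
            return UnivariateResult(feature, "fisher_exact", float(stat),
                                    float(p))
        chi2, p, _, _ = sps.chi2_contingency(table)
        return UnivariateResult(feature, "chi_square", float(chi2), float(p))
    raise ValueError(f"unknown variable kind {kind!r}")


def spearman_vs_ris(feature_values, ris_values,
                    feature: str = "") -> UnivariateResult:
    """Spearman rank correlation of a feature against RIS.

    pCR patients enter with RIS = 0 (a tied block handled by midranks).
    A constant vector has no rank ordering: rho is NaN and the result is
    flagged through a NaN p-value.
    """
    x = np.asarray(feature_values, dtype=float)
    r = np.asarray(ris_values, dtype=float)
    if len(x) != len(r):
        raise ValueError("paired vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(r) == 0:
        return UnivariateResult(feature, "spearman", float("nan"),
                                float("nan"), rho=float("nan"))
    rho, p = sps.spearmanr(x, r)
    return UnivariateResult(feature, "spearman", float(rho), float(p),
                            rho=float(rho))


def importance_report(weights: dict[str, float], top: int = 3) -> dict:
    """Ranked favorable (positive) and adverse (negative) LASSO weights.

    Returns the full signed ranking plus the top-``top`` features on
    each side, ready for importance bar plots.
    """
    ranked = sorted(weights.items(), key=lambda kv: -kv[1])
    favorable = [(n, w) for n, w in ranked if w > 0][:top]
    adverse = sorted(
        [(n, w) for n, w in weights.items() if w < 0], key=lambda kv: kv[1]
    )[:top]
    return {"ranked": ranked, "favorable": favorable, "adverse": adverse}


def univariate_table(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "pcr",
    ris_col: str = "ris_cm",
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Univariate screen of many features: group test + RIS correlation.

    One row per feature with the group-comparison statistic/p-value and
    the Spearman correlation against RIS; the ``n_tests`` attribute of
    the returned frame records how many hypotheses were examined (no
    multiplicity correction is applied).
    """
    kinds = kinds or {}
    rows = []
    for name in features:
        kind = kinds.get(name, "continuous")
        values = table[name].to_numpy()
        mask = ~pd.isna(values)
        res = compare_groups(values[mask], table[group_col].to_numpy()[mask],
                             kind=kind, feature=name)
        row = {
            "feature": name,
            "test": res.test,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.significant,
        }
        if ris_col in table.columns and kind == "continuous":
            sp = spearman_vs_ris(values[mask],
                                 table[ris_col].to_numpy()[mask], name)
            row["rho"] = sp.rho
            row["rho_p_value"] = sp.p_value
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out
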