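"""Group comparison, correlation screening and PCA over the variety table.

The variety table holds one row per variety: a commercial-type label plus
the 16 analysis variables (eGI, RDS, SDS, RS, TS, k_RVA, AMYL, FAT, FIBER,
PRTD, Tg, VPEAK, SB, WUp, VER, SL).  Three analyses mirror common practice
in grain-quality studies:

* one-way ANOVA per variable with all-pairs Tukey–Kramer HSD comparisons
  (studentized-range based, valid for unbalanced groups) summarised as a
  compact letter display — groups sharing a letter are not significantly
  different;
* a Pearson correlation matrix with per-pair two-sided significance
  filtering at level alpha (no family-wise correction by default, an
  optional Bonferroni mode is exposed);
* standardized principal component analysis with loadings, scores and
  variance-explained fractions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA

from .config import VARIABLES

__all__ = [
    "GroupComparison",
    "CorrelationReport",
    "PCAResult",
    "compare_groups",
    "correlation_report",
    "pca",
    "compact_letter_display",
]


@dataclass(frozen=True)
class GroupComparison:
    """Per-(variable, group) summary with Tukey letters and per-variable ANOVA.

    ``summary`` has a (variable, group) MultiIndex with columns
    mean/sd/n/letters; ``anova`` is indexed by variable with columns F/p;
    ``tukey_p`` maps variable -> DataFrame of pairwise Tukey p-values.
    """

    summary: pd.DataFrame
    anova: pd.DataFrame
    tukey_p: dict[str, pd.DataFrame]
    alpha: float


@dataclass(frozen=True)
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    @property
    def display(self) -> pd.DataFrame:
        """Correlations rounded to 1 decimal, blanked where not significant."""
        return self.r.round(1).where(self.significant)


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_ratio: np.ndarray


def compact_letter_display(
    means: dict[str, float], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are ordered by descending mean; letters are assigned so that two
    groups share a letter exactly when they are NOT in
    ``significant_pairs``.
    """
    groups = sorted(means, key=lambda g: -means[g])
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant_pairs, key=lambda p: sorted(p)):
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another column
        columns = [
            c for i, c in enumerate(new_cols)
            if c and not any(i != j and c < d or (c == d and i > j)
                             for j, d in enumerate(new_cols))
        ]
    # order columns by their best (highest-mean) member for a..z assignment
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def _tukey_pvalues(samples: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*samples)
    return pd.DataFrame(res.pvalue, index=labels, columns=labels)


def compare_groups(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "type",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA + Tukey–Kramer HSD letters for each variable.

    Groups with a single observation are excluded from testing and letter
    assignment (their mean is still reported).  Rows with a missing value
    of a variable are dropped listwise for that variable.
    """
    if variables is None:
        variables = [v for v in VARIABLES if v in table.columns]
    counts = table[group_col].value_counts()
    usable = [g for g in counts.index if counts[g] >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    summary_rows = []
    anova_rows = []
    tukey_p: dict[str, pd.DataFrame] = {}
    for var in variables:
        sub = table[[group_col, var]].dropna()
        grouped = {g: sub.loc[sub[group_col] == g, var].to_numpy(float)
                   for g in counts.index if g in set(sub[group_col])}
        test_groups = [g for g in usable if g in grouped and grouped[g].size >= 2]
        samples = [grouped[g] for g in test_groups]
        pooled_var = float(np.mean([s.var(ddof=1) for s in samples])) if samples else 0.0
        if pooled_var == 0.0:
            warnings.warn(
                f"{var}: zero pooled variance; all groups share one letter",
                RuntimeWarning, stacklevel=2,
            )
            f_stat, p_val = np.nan, np.nan
            letters = {g: "a" for g in test_groups}
            tukey_p[var] = pd.DataFrame(
                np.ones((len(test_groups), len(test_groups))),
                index=test_groups, columns=test_groups,
            )
        else:
            f_stat, p_val = sps.f_oneway(*samples)
            pmat = _tukey_pvalues(samples, test_groups)
            tukey_p[var] = pmat
            sig = {
                frozenset((a, b))
                for a, b in itertools.combinations(test_groups, 2)
                if pmat.loc[a, b] <= alpha
            }
            means = {g: float(grouped[g].mean()) for g in test_groups}
            letters = compact_letter_display(means, sig)
        anova_rows.append({"variable": var, "F": f_stat, "p": p_val})
        for g, vals in grouped.items():
            summary_rows.append({
                "variable": var,
                "group": g,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
                "n": int(vals.size),
                "letters": letters.get(g, ""),
            })
    summary = pd.DataFrame(summary_rows).set_index(["variable", "group"])
    anova = pd.DataFrame(anova_rows).set_index("variable")
    return GroupComparison(summary=summary, anova=anova, tukey_p=tukey_p, alpha=alpha)


def correlation_report(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CorrelationReport:
    """Pairwise-complete Pearson correlations with significance filtering.

    Per-pair two-sided p-values come from the exact t transform of r with
    n-2 degrees of freedom.  Constant columns yield missing correlations.
    """
    if variables is None:
        variables = [v for v in VARIABLES if v in table.columns]
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    m = k * (k - 1) // 2
    for a, b in itertools.combinations(variables, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rv, pv = np.nan, np.nan
        else:
            rv, pv = sps.pearsonr(sub[a], sub[b])
            if bonferroni:
                pv = min(1.0, pv * m)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    significant = p <= alpha
    np.fill_diagonal(significant.values, True)
    return CorrelationReport(r=r, p=p, significant=significant, alpha=alpha)


def pca(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    standardize: bool = True,
    index_col: str = "variety",
) -> PCAResult:
    """Standardized PCA of the variety table.

    Rows with missing values are dropped listwise (logged).  Each loading
    column is sign-fixed so its largest-magnitude entry is positive, and the
    variance-explained fractions are reported over all components (they sum
    to 1).
    """
    if variables is None:
        variables = [v for v in VARIABLES if v in table.columns]
    data = table.set_index(index_col)[variables] if index_col in table.columns \
        else table[variables]
    complete = data.dropna()
    if len(complete) < len(data):
        warnings.warn(
            f"PCA: dropped {len(data) - len(complete)} rows with missing values",
            RuntimeWarning, stacklevel=2,
        )
    x = complete.to_numpy(float)
    mu = x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        zero = [v for v, s in zip(variables, sd) if s == 0]
        if zero:
            raise ValueError(f"zero-variance column(s) under standardization: {zero}")
        x = (x - mu) / sd
    else:
        x = x - mu
    model = _SkPCA(n_components=min(x.shape))
    scores = model.fit_transform(x)
    components = model.components_  # rows = axes
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(components.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(components.T, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        variance_ratio=model.explained_variance_ratio_,
    )
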