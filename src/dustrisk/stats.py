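"""Correlation screening and group-mean comparison for dust surveys.

Pearson correlation with two-tailed significance (t transform,
``t = r*sqrt(n-2)/sqrt(1-r^2)`` on n-2 degrees of freedom) and the
conventional strength bands on |r|: <0.40 weak, 0.40-0.69 moderate,
0.70-0.89 strong, 0.90-1.00 very strong.  Group means are compared with
pairwise Welch t-tests (robust to the very unequal group sizes of a small
survey) under Holm correction, summarized as a compact letter display:
levels sharing a letter are statistically indistinguishable at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_model import StudyTable

STRENGTH_BANDS = (
    (0.40, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
)


def classify_correlation(r: float) -> str:
    """Strength label on |r|; sign is reported separately by callers."""
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    magnitude = abs(r)
    for bound, label in STRENGTH_BANDS:
        if magnitude < bound:
            return label
    return "very strong"


def significance_stars(p: float, levels: tuple[float, ...] = (0.05, 0.01)) -> str:
    """'' / '*' / '**' annotation at the 0.05 and 0.01 levels."""
    stars = ""
    for level in sorted(levels, reverse=True):
        if p < level:
            stars += "*"
    return stars


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pairwise-complete Pearson r and two-tailed p for two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson screen over a set of survey variables.

    ``r``/``p``/``n`` are symmetric DataFrames; ``labels`` hold strength
    bands, ``stars`` the significance annotation.  Cells where a variable
    was constant (correlation undefined) are listed in ``undefined`` and
    hold NaN — they are flagged, not silently propagated.
    """

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    labels: pd.DataFrame
    stars: pd.DataFrame
    undefined: list[tuple[str, str]]

    def annotated(self) -> pd.DataFrame:
        """r rounded to 2 dp with star annotations, publication-style."""
        out = pd.DataFrame("", index=self.variables, columns=self.variables)
        for i in self.variables:
            for j in self.variables:
                value = self.r.loc[i, j]
                if np.isnan(value):
                    out.loc[i, j] = "n.d."
                else:
                    out.loc[i, j] = f"{value:.2f}{self.stars.loc[i, j]}"
        return out


def correlation_matrix(
    study: StudyTable | pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pearson r/p/n matrices over elements and bacterial loads.

    Accepts a StudyTable (uses concentrations plus TB/EB) or any numeric
    DataFrame.  Missing values are handled pairwise-complete with per-cell
    n reported.
    """
    frame = (
        study.variable_frame() if isinstance(study, StudyTable) else study
    )
    if variables is None:
        variables = list(frame.columns)
    variables = list(variables)
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    undefined: list[tuple[str, str]] = []
    for a in variables:
        n.loc[a, a] = int(np.isfinite(frame[a].to_numpy(dtype=float)).sum())
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variables[i], variables[j]
            x = frame[a].to_numpy(dtype=float)
            y = frame[b].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n.loc[a, b] = n.loc[b, a] = int(keep.sum())
            try:
                rij, pij = pearson_r_p(x, y)
            except ValueError:
                undefined.append((a, b))
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    labels = r.map(
        lambda v: classify_correlation(v) if np.isfinite(v) else "undefined"
    )
    stars = p.map(
        lambda v: significance_stars(v) if np.isfinite(v) else ""
    )
    np.fill_diagonal(stars.values, "")
    return CorrelationMatrix(
        variables=variables, r=r, p=p, n=n, labels=labels, stars=stars,
        undefined=undefined,
    )


@dataclass
class GroupComparison:
    """Group means with a compact letter display.

    Levels sharing a letter are not significantly different under pairwise
    Welch t-tests with Holm correction at ``alpha``.
    """

    attribute: str
    element: str
    levels: list[str]
    means: Mapping[str, float]
    n: Mapping[str, int]
    letters: Mapping[str, str]
    p_values: Mapping[tuple[str, str], float]
    alpha: float
    excluded: list[str]


def _compact_letter_display(
    levels: Sequence[str], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Greedily grows letter groups (subsets of levels with no significant
    pair inside), then absorbs redundant groups; letters are assigned in
    level order for determinism.
    """
    def compatible(level: str, group: set[str]) -> bool:
        return all(
            (level, other) not in distinct and (other, level) not in distinct
            for other in group
            if other != level
        )

    groups: list[set[str]] = []
    for level in levels:
        placed = False
        for group in groups:
            if compatible(level, group):
                group.add(level)
                placed = True
        if not placed:
            # seed a new group and pull in every level that fits it, so a
            # middle level can still share a letter with a later extreme
            group = {level}
            for other in levels:
                if other != level and compatible(other, group):
                    group.add(other)
            groups.append(group)
    # absorb groups contained in another
    groups = [
        g for i, g in enumerate(groups)
        if not any(i != j and g < other for j, other in enumerate(groups))
    ]
    # deduplicate while preserving order
    unique: list[set[str]] = []
    for g in groups:
        if g not in unique:
            unique.append(g)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {level: "" for level in levels}
    for symbol, group in zip(alphabet, unique):
        for level in levels:
            if level in group:
                letters[level] += symbol
    return letters


def compare_groups(
    study: StudyTable | pd.DataFrame,
    attribute: str,
    element: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare an element's mean across the levels of a habitat attribute.

    Pairwise Welch t-tests (unequal variances, unequal n) with Holm
    correction; levels with fewer than 2 samples are excluded with a note.
    Accepts a StudyTable or a long DataFrame with columns
    ``[attribute, element]``.
    """
    if isinstance(study, StudyTable):
        frame = study.to_dataframe()[[attribute, element]].dropna()
    else:
        frame = study[[attribute, element]].dropna()
    groups = {
        str(level): sub[element].to_numpy(dtype=float)
        for level, sub in frame.groupby(attribute, sort=True)
    }
    excluded = [level for level, v in groups.items() if len(v) < 2]
    groups = {level: v for level, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError(
            f"compare_groups needs >= 2 levels with >= 2 samples each "
            f"(usable: {list(groups)})"
        )
    levels = list(groups)
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels)) for j in range(i + 1, len(levels))
    ]
    raw_p = []
    for a, b in pairs:
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
            # Welch t is undefined for two zero-variance samples; identical
            # constants are indistinguishable, distinct constants differ.
            raw_p.append(1.0 if groups[a][0] == groups[b][0] else 0.0)
        else:
            raw_p.append(
                float(sps.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
            )
    if pairs:
        adjusted = multipletests(raw_p, alpha=alpha, method="holm")[1]
    else:
        adjusted = []
    p_values = {pair: float(p) for pair, p in zip(pairs, adjusted)}
    distinct = {pair for pair, p in p_values.items() if p < alpha}
    letters = _compact_letter_display(levels, distinct)
    return GroupComparison(
        attribute=attribute,
        element=element,
        levels=levels,
        means={lv: float(np.mean(groups[lv])) for lv in levels},
        n={lv: int(len(groups[lv])) for lv in levels},
        letters=letters,
        p_values=p_values,
        alpha=alpha,
        excluded=excluded,
    )


def group_summary_table(
    study: StudyTable,
    attribute: str,
    elements: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-level means with significance letters, one column per element."""
    rows: dict[str, dict[str, str]] = {}
    for element in elements:
        try:
            comparison = compare_groups(study, attribute, element, alpha)
        except ValueError:
            continue
        for level in comparison.levels:
            cell = f"{comparison.means[level]:.4g}"
            letter = comparison.letters[level]
            # only annotate when some pair actually separated
            if any(p < alpha for p in comparison.p_values.values()):
                cell += f" {letter}"
            rows.setdefault(level, {})[element] = cell
    return pd.DataFrame(rows).T.sort_index()
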