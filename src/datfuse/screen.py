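"""Per-feature unequal-variance screening of biomarker sources.

Each biomarker test is compared between the two diagnostic groups with
Welch's unequal-variance two-sample t-test (Satterthwaite degrees of
freedom, two-sided p). A whole source (CSF, RNA, Serum, ...) is then ranked
by its single most significant member feature — the minimum p across its
tests — and features are flagged at the 0.05 level.

This screening is descriptive and deliberately applies **no multiple-testing
correction**: its role is to decide whether an entire source carries any
class signal worth feeding to the ensemble, not to make per-feature
inferential claims. Missing values are handled pairwise-complete per
feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WelchResult", "ScreenResult", "welch_test", "screen_source", "screen_sources"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature Welch results for one source plus its source-level rank."""

    source: str
    table: pd.DataFrame        # feature, statistic, df, p, significant
    min_p: float
    min_p_feature: str

    @property
    def significant(self) -> bool:
        return bool(self.min_p < SIGNIFICANCE_LEVEL)


def welch_test(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Requires at least two finite values per group and a nonzero variance in
    at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constants: no evidence of any difference
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        raise ValueError("both groups constant with different means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def screen_source(table: pd.DataFrame, labels: pd.Series, source: str = "") -> ScreenResult:
    """Screen every feature of one source table against the class labels.

    ``table`` is subjects × tests (NaN = missing), indexed by subject id;
    ``labels`` must cover those subjects with exactly two classes. Each
    feature is tested on its pairwise-complete subjects.
    """
    if table.shape[1] == 0 or table.shape[0] == 0:
        raise ValueError("empty source table")
    labels = labels.loc[table.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask_a = (labels == classes[0]).to_numpy()
    rows = []
    for feature in table.columns:
        col = table[feature].to_numpy(dtype=float)
        try:
            res = welch_test(col[mask_a], col[~mask_a])
        except ValueError as err:
            raise ValueError(f"feature {feature!r}: {err}") from err
        rows.append((feature, res.statistic, res.df, res.pvalue,
                     res.pvalue < SIGNIFICANCE_LEVEL))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "df", "p", "significant"])
    best = out.loc[out["p"].idxmin()]
    return ScreenResult(
        source=source or "source",
        table=out,
        min_p=float(best["p"]),
        min_p_feature=str(best["feature"]),
    )


def screen_sources(
    sources: dict[str, pd.DataFrame], labels: pd.Series
) -> pd.DataFrame:
    """Screen several sources; one long table ranked by source minimum p."""
    frames = []
    for name, table in sources.items():
        result = screen_source(table, labels, source=name)
        frame = result.table.assign(source=name, source_min_p=result.min_p)
        frames.append(frame)
    combined = pd.concat(frames, ignore_index=True)
    return combined.sort_values(
        ["source_min_p", "source", "p"], ignore_index=True
    )[["source", "feature", "statistic", "df", "p", "significant", "source_min_p"]]
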