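"""Untargeted differential screen and Monte-Carlo power analysis.

The screen mirrors the standard two-group untargeted metabolomics
workflow: keep features quantified in every sample of at least one
group, Welch-test log2 intensities feature-wise, control the FDR by
Benjamini-Hochberg, and call features that clear both a fold-change
and an FDR threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "ScreenConfig",
    "ScreenResult",
    "presence_filter",
    "volcano_screen",
    "power_sample_size",
]


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with group labels.

    ``intensities`` is indexed by feature id (conventionally
    ``mass@rt``); missing values are NaN.
    """

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if not self.intensities.index.is_unique:
            raise ValueError("feature ids must be unique")
        if set(self.intensities.columns) != set(self.groups.index):
            raise ValueError("group labels must cover exactly the sample columns")
        self.groups = self.groups.loc[self.intensities.columns]
        if self.groups.nunique() < 2:
            raise ValueError("need at least 2 groups")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups))

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass(frozen=True)
class ScreenConfig:
    """Volcano thresholds: fold change and FDR, both two-sided."""

    fold_change: float = 2.0
    fdr: float = 0.005
    log_transform: bool = True
    multiple_testing: str = "fdr_bh"

    def __post_init__(self) -> None:
        if self.fold_change <= 0 or self.fdr <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ScreenResult:
    """Per-feature differential statistics and the significant count."""

    table: pd.DataFrame
    config: ScreenConfig
    groups: tuple[str, str]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def presence_filter(table: FeatureTable) -> FeatureTable:
    """Keep features with no missing value in at least one complete group."""
    keep = pd.Series(False, index=table.intensities.index)
    for g in table.group_names:
        cols = table.samples_of(g)
        keep |= table.intensities[cols].notna().all(axis=1)
    if not keep.any():
        warnings.warn("presence filter removed every feature", stacklevel=2)
    return FeatureTable(table.intensities.loc[keep].copy(), table.groups.copy())


def volcano_screen(table: FeatureTable, config: ScreenConfig | None = None) -> ScreenResult:
    """Two-group Welch screen with BH adjustment and joint thresholds.

    Fold change is the ratio of raw group means (first group over
    second); the test runs on log2 intensities.  A feature is
    significant iff |log2 FC| > log2(threshold) and adjusted p < FDR.
    """
    config = config or ScreenConfig()
    groups = table.group_names
    if len(groups) != 2:
        raise ValueError(f"volcano screen needs exactly 2 groups, got {len(groups)}")
    ga, gb = groups
    a = table.intensities[table.samples_of(ga)].to_numpy(dtype=float)
    b = table.intensities[table.samples_of(gb)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_a / mean_b)
    if config.log_transform:
        ta = np.log2(np.where(a > 0, a, np.nan))
        tb = np.log2(np.where(b > 0, b, np.nan))
    else:
        ta, tb = a, b
    enough = (np.sum(~np.isnan(ta), axis=1) >= 2) & (np.sum(~np.isnan(tb), axis=1) >= 2)
    stat = np.full(a.shape[0], np.nan)
    pval = np.full(a.shape[0], np.nan)
    if enough.any():
        res = scipy.stats.ttest_ind(
            ta[enough], tb[enough], axis=1, equal_var=False, nan_policy="omit"
        )
        stat[enough] = res.statistic
        pval[enough] = res.pvalue
    padj = np.full(a.shape[0], np.nan)
    tested = ~np.isnan(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method=config.multiple_testing)[1]
    log2_thresh = np.log2(config.fold_change)
    significant = tested & (np.abs(log2fc) > log2_thresh) & (padj < config.fdr)
    out = pd.DataFrame(
        {
            f"mean_{ga}": mean_a,
            f"mean_{gb}": mean_b,
            "log2_fc": log2fc,
            "t_stat": stat,
            "p_value": pval,
            "p_adjusted": padj,
            "significant": significant,
        },
        index=table.intensities.index,
    )
    return ScreenResult(table=out, config=config, groups=(ga, gb))


def power_sample_size(
    group_means: tuple[float, float],
    group_sds: tuple[float, float],
    alpha: float = 0.05,
    target_power: float = 0.80,
    reps: int = 2000,
    seed: int = 0,
    max_n: int = 100,
) -> int:
    """Smallest per-group n at which the Welch test reaches *target_power*.

    Monte-Carlo estimate: for n = 2, 3, ... simulate *reps* two-group
    normal datasets at the given means/SDs and count rejections at
    level *alpha*.
    """
    if min(group_sds) <= 0:
        raise ValueError("group SDs must be positive")
    if not (0 < alpha < 1 and 0 < target_power < 1):
        raise ValueError("alpha and target power must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    for n in range(2, max_n + 1):
        a = rng.normal(group_means[0], group_sds[0], size=(reps, n))
        b = rng.normal(group_means[1], group_sds[1], size=(reps, n))
        p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        if np.mean(p < alpha) >= target_power:
            return n
    raise RuntimeError(
        f"target power {target_power} not reached by n = {max_n}; effect too small"
    )
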