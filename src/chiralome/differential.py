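"""Per-feature group comparisons, significance tiers, and pair-level gating.

Tests are Welch t-tests by default (pooled-variance Student by config); the
one-tailed mode follows the observed direction of the mean difference unless
a fixed direction is configured.  All p-values are reported unadjusted — no
multiple-testing correction is applied anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chiralome.config import AnalysisConfig
from chiralome.io_formats import FeatureTable
from chiralome.chiral_pairing import EnantiomerPair

TIER_SIGNIFICANT = "significant"
TIER_BORDERLINE = "borderline"
TIER_NOT_SIGNIFICANT = "not_significant"
TIER_UNTESTED = "untested"

DIR_UP = "up_in_positive"
DIR_DOWN = "down_in_positive"
DIR_NONE = "none"


@dataclass
class DifferentialResult:
    feature_id: str
    p_value: float
    direction: str
    log2_fc: float
    tier: str
    n_pos: int
    n_neg: int
    note: str = ""


def _clean(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def one_tailed_ttest(
    x: Sequence[float],
    y: Sequence[float],
    tail_mode: str = "observed",
    equal_var: bool = False,
) -> tuple[float, str]:
    """One-tailed t-test of x (positive group) against y (negative group).

    ``tail_mode='observed'`` reports the one-tailed probability in the
    direction of the observed mean difference (two-tailed p halved); this is
    anti-conservative and flagged as such in the run manifest.  Fixed modes
    'greater'/'less' test the stated direction of x relative to y.

    Returns ``(p_value, direction)`` where direction is the observed sign of
    mean(x) - mean(y).
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs >= 2 values per group")
    diff = float(np.mean(x) - np.mean(y))
    direction = DIR_UP if diff > 0 else DIR_DOWN if diff < 0 else DIR_NONE

    if np.std(x) == 0 and np.std(y) == 0:
        # degenerate: no within-group variance
        p_two = 1.0 if diff == 0 else 0.0
    else:
        p_two = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)

    if tail_mode == "observed":
        p = 0.5 if direction == DIR_NONE else p_two / 2.0
    elif tail_mode in ("greater", "less"):
        alt = tail_mode
        if np.std(x) == 0 and np.std(y) == 0:
            if diff == 0:
                p = 0.5
            else:
                p = 0.0 if (diff > 0) == (alt == "greater") else 1.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=equal_var, alternative=alt).pvalue)
    else:
        raise ValueError(f"unknown tail_mode {tail_mode!r}")
    return p, direction


def two_tailed_ttest(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> float:
    """Two-tailed unpaired t-test p-value (Welch by default)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs >= 2 values per group")
    if np.std(x) == 0 and np.std(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def log2_fold_change(x: Sequence[float], y: Sequence[float]) -> float:
    """log2 of the ratio of group means (x over y); NaN when a mean is <= 0
    or a group is entirely missing."""
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    mx, my = float(np.mean(x)), float(np.mean(y))
    if mx <= 0 or my <= 0:
        return float("nan")
    return math.log2(mx / my)


def classify_tier(p: float, config: AnalysisConfig | None = None) -> str:
    """'significant' (p < alpha), 'borderline' (alpha <= p < borderline_hi),
    else 'not_significant'."""
    config = config or AnalysisConfig()
    if math.isnan(p):
        return TIER_UNTESTED
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if p < config.alpha:
        return TIER_SIGNIFICANT
    if p < config.borderline_hi:
        return TIER_BORDERLINE
    return TIER_NOT_SIGNIFICANT


def _test_vectors(
    x: np.ndarray, y: np.ndarray, feature_id: str, config: AnalysisConfig, note: str = ""
) -> DifferentialResult:
    xc, yc = _clean(x), _clean(y)
    if len(xc) < config.min_per_group or len(yc) < config.min_per_group:
        return DifferentialResult(
            feature_id=feature_id,
            p_value=float("nan"),
            direction=DIR_NONE,
            log2_fc=log2_fold_change(xc, yc) if len(xc) and len(yc) else float("nan"),
            tier=TIER_UNTESTED,
            n_pos=len(xc),
            n_neg=len(yc),
            note=(note + "; " if note else "") + "too few values",
        )
    p, direction = one_tailed_ttest(
        xc, yc, tail_mode=config.tail_mode, equal_var=config.equal_var
    )
    return DifferentialResult(
        feature_id=feature_id,
        p_value=p,
        direction=direction,
        log2_fc=log2_fold_change(xc, yc),
        tier=classify_tier(p, config),
        n_pos=len(xc),
        n_neg=len(yc),
        note=note,
    )


def run_differential(
    table: FeatureTable, config: AnalysisConfig | None = None
) -> list[DifferentialResult]:
    """Test every feature: positive vs negative group, one-tailed, log2 FC."""
    config = config or AnalysisConfig()
    pos = table.group_samples("positive")
    neg = table.group_samples("negative")
    xmat = table.intensities[pos].to_numpy(dtype=float)
    ymat = table.intensities[neg].to_numpy(dtype=float)
    return [
        _test_vectors(xmat[i], ymat[i], str(fid), config)
        for i, fid in enumerate(table.feature_ids)
    ]


def results_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": r.feature_id,
            "p_value": r.p_value,
            "log2_fc": r.log2_fc,
            "tier": r.tier,
            "direction": r.direction,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "p_value", "log2_fc", "tier", "direction",
            "n_pos", "n_neg", "note",
        ],
    )


def volcano_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    """log2 FC vs -log10 p for plotting."""
    frame = results_frame(results)
    frame["neg_log10_p"] = -np.log10(frame["p_value"])
    return frame[["feature_id", "log2_fc", "neg_log10_p", "tier"]]


def gate_pairs(
    pairs: Iterable[EnantiomerPair],
    results: Mapping[str, DifferentialResult] | Iterable[DifferentialResult],
) -> list[EnantiomerPair]:
    """Mark pairs where at least one member's tier is 'significant'.

    Borderline does not satisfy the gate.  Members without a (tested)
    result count as not significant.
    """
    if not isinstance(results, Mapping):
        results = {r.feature_id: r for r in results}
    gated = []
    for pair in pairs:
        passed = any(
            fid in results and results[fid].tier == TIER_SIGNIFICANT
            for fid in pair.members
        )
        gated.append(replace(pair, gate_passed=passed))
    return gated


def pooled_test(
    pair: EnantiomerPair, table: FeatureTable, config: AnalysisConfig | None = None
) -> DifferentialResult:
    """Test the per-sample sum of a pair's two features (the E1+E2 pool).

    If one member is entirely missing, the pool falls back to the other
    member and the result is flagged.
    """
    config = config or AnalysisConfig()
    if pair.e1 is None or pair.e2 is None:
        raise ValueError("pair must be labeled before pooled testing")
    a = table.intensities.loc[pair.e1]
    b = table.intensities.loc[pair.e2]
    note = ""
    if a.isna().all() and b.isna().all():
        raise ValueError(f"both members of pair ({pair.e1}, {pair.e2}) are all-missing")
    if a.isna().all():
        pooled, note = b, f"pool fallback: {pair.e1} all-missing"
    elif b.isna().all():
        pooled, note = a, f"pool fallback: {pair.e2} all-missing"
    else:
        pooled = a + b  # a sample missing either member is missing in the pool
    pos = table.group_samples("positive")
    neg = table.group_samples("negative")
    return _test_vectors(
        pooled[pos].to_numpy(dtype=float),
        pooled[neg].to_numpy(dtype=float),
        f"{pair.e1}+{pair.e2}",
        config,
        note=note,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (W, two-sided p).

    W is the rank sum of ``x`` in the combined sample.  The p-value comes
    from the exact permutation distribution when the combined n is <= 20 and
    there are no ties, and from the tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1 = len(x)
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic + n1 * (n1 + 1) / 2.0)  # U1 -> rank sum of x
    return w, float(min(res.pvalue, 1.0))
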