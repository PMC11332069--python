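"""Enantiomer-pair detection, E1/E2 labeling, QC swap verification, annotation.

After chiral derivatization the two enantiomers of a compound appear as two
aligned features with (near-)identical m/z and a retention-time offset.  Two
features whose m/z differ by less than ``ppm_max`` ppm and whose RTs differ
by less than ``rt_pair_max`` minutes (both strict) are candidate enantiomer
pairs.  Because the (+)- and (-)-forms of the derivatizing agent invert the
elution order of a true enantiomer pair, the intensity ratio at the pair's
two RT positions inverts between the plus- and minus-agent QC pools; that
inversion is the swap-verification signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chiralome.config import AnalysisConfig
from chiralome.io_formats import FeatureTable, StandardsLibrary

logger = logging.getLogger(__name__)

SWAP_VERIFIED = "verified"
SWAP_NOT_VERIFIED = "not_verified"
SWAP_UNTESTABLE = "untestable"


@dataclass
class EnantiomerPair:
    """A matched feature duo; ``e1``/``e2`` are abundance-ordered labels."""

    feature_a: str
    feature_b: str
    ppm_diff: float
    rt_diff: float
    e1: str | None = None
    e2: str | None = None
    swap_status: str = SWAP_UNTESTABLE
    gate_passed: bool | None = None

    @property
    def members(self) -> tuple[str, str]:
        return (self.feature_a, self.feature_b)


@dataclass
class Annotation:
    """A feature matched to a standards-library entry."""

    feature_id: str
    compound: str
    enantiomer: str
    ppm_error: float
    rt_error: float


def ppm_difference(mz_a: float, mz_b: float) -> float:
    """Relative m/z difference in parts per million.

    The denominator is the mean of the two masses; at the few-ppm scale the
    choice of denominator is immaterial.
    """
    if mz_a <= 0 or mz_b <= 0:
        raise ValueError(f"masses must be positive, got ({mz_a}, {mz_b})")
    return abs(mz_a - mz_b) / ((mz_a + mz_b) / 2.0) * 1e6


def _candidate_pairs(
    features: pd.DataFrame, ppm_max: float, rt_max: float
) -> list[tuple[float, float, str, str]]:
    """All unordered pairs passing the strict ppm and RT windows.

    Sort-by-mass sweep keeps this near-linear for realistic tables.
    """
    order = np.argsort(features["mz"].to_numpy(), kind="stable")
    mz = features["mz"].to_numpy()[order]
    rt = features["rt"].to_numpy()[order]
    ids = features.index.to_numpy()[order]
    out: list[tuple[float, float, str, str]] = []
    n = len(mz)
    for i in range(n):
        # features beyond mz[i] * (1 + ppm_max*1e-6) cannot pair with i
        hi = mz[i] * (1 + ppm_max * 1e-6) * (1 + 1e-12)
        j = i + 1
        while j < n and mz[j] <= hi:
            ppm = ppm_difference(mz[i], mz[j])
            dt = abs(rt[i] - rt[j])
            if ppm < ppm_max and 0.0 < dt < rt_max:
                a, b = sorted((str(ids[i]), str(ids[j])))
                out.append((ppm, dt, a, b))
            j += 1
    return out


def detect_enantiomer_candidates(
    table: FeatureTable, config: AnalysisConfig | None = None
) -> list[EnantiomerPair]:
    """Greedy maximal pairing of features within the ppm/RT windows.

    All qualifying unordered pairs are ranked by ascending ppm difference,
    then ascending RT difference, then lexicographic ids; pairs are accepted
    greedily so that each feature appears in at most one returned pair.
    Conflicts (a feature qualifying for several pairs) are logged.
    """
    config = config or AnalysisConfig()
    candidates = _candidate_pairs(table.features, config.ppm_max, config.rt_pair_max)
    candidates.sort()
    used: set[str] = set()
    pairs: list[EnantiomerPair] = []
    n_conflicts = 0
    for ppm, dt, a, b in candidates:
        if a in used or b in used:
            n_conflicts += 1
            continue
        used.update((a, b))
        pairs.append(EnantiomerPair(feature_a=a, feature_b=b, ppm_diff=ppm, rt_diff=dt))
    if n_conflicts:
        logger.info(
            "pairing resolved %d conflicting candidate pairs greedily", n_conflicts
        )
    return pairs


def assign_enantiomer_labels(
    pair: EnantiomerPair, table: FeatureTable
) -> EnantiomerPair:
    """Set ``e1`` (lower mean abundance over study samples) and ``e2``.

    Equal means fall back to elution order: the earlier-RT feature is e1.
    """
    study = table.study_samples()
    means = table.intensities.loc[list(pair.members), study].mean(axis=1, skipna=True)
    if means.isna().any():
        missing = means.index[means.isna()][0]
        raise ValueError(
            f"feature {missing!r} has no non-missing study-sample intensity"
        )
    ma, mb = float(means[pair.feature_a]), float(means[pair.feature_b])
    if ma < mb:
        e1, e2 = pair.feature_a, pair.feature_b
    elif mb < ma:
        e1, e2 = pair.feature_b, pair.feature_a
    else:
        rts = table.features.loc[list(pair.members), "rt"]
        e1 = str(rts.idxmin())
        e2 = pair.feature_b if e1 == pair.feature_a else pair.feature_a
    return replace(pair, e1=e1, e2=e2)


def _qc_intensity(table: FeatureTable, feature: str, chirality: str) -> float:
    """Mean intensity of a feature over the QC pools of one chirality.

    NaN if no such QC exists or any of its values is missing.
    """
    qcs = table.qc_samples(chirality)
    if not qcs:
        return float("nan")
    vals = table.intensities.loc[feature, qcs].to_numpy(dtype=float)
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.mean())


def verify_label_swap(
    pair: EnantiomerPair, table: FeatureTable, config: AnalysisConfig | None = None
) -> str:
    """Check for elution-order inversion between plus- and minus-agent QCs.

    With R+ = I(e1)/I(e2) in the plus-QC and R- the same ratio in the
    minus-QC (positions fixed by the study samples' RTs), a genuine
    enantiomer pair shows log2(R+) and log2(R-) of opposite sign, each with
    magnitude at least ``swap_tau``.  Returns one of 'verified',
    'not_verified', 'untestable'.
    """
    config = config or AnalysisConfig()
    if pair.e1 is None or pair.e2 is None:
        raise ValueError("pair must be labeled (e1/e2) before swap verification")
    values = [
        _qc_intensity(table, f, c)
        for f in (pair.e1, pair.e2)
        for c in ("plus", "minus")
    ]
    e1_plus, e1_minus, e2_plus, e2_minus = values
    if any(math.isnan(v) or v <= 0 for v in values):
        return SWAP_UNTESTABLE
    log_r_plus = math.log2(e1_plus / e2_plus)
    log_r_minus = math.log2(e1_minus / e2_minus)
    inverted = log_r_plus * log_r_minus < 0
    strong = min(abs(log_r_plus), abs(log_r_minus)) >= config.swap_tau
    return SWAP_VERIFIED if (inverted and strong) else SWAP_NOT_VERIFIED


def annotate_features(
    table: FeatureTable,
    library: StandardsLibrary,
    config: AnalysisConfig | None = None,
) -> list[Annotation]:
    """Match features to standards by accurate mass and retention time.

    Each feature takes the library entry minimizing the ppm error among
    entries within ``ppm_max`` and ``annotation_rt_tol``; ties break on
    |RT error|.  Features with no qualifying entry are left unannotated
    (reported as 'unknown' by :func:`annotation_frame`).
    """
    config = config or AnalysisConfig()
    if len(library) == 0:
        raise ValueError("standards library is empty")
    lib_mz = library.entries["expected_mz"].to_numpy(dtype=float)
    lib_rt = library.entries["expected_rt"].to_numpy(dtype=float)
    out: list[Annotation] = []
    for fid, row in table.features.iterrows():
        ppm_err = np.abs(row["mz"] - lib_mz) / ((row["mz"] + lib_mz) / 2.0) * 1e6
        rt_err = row["rt"] - lib_rt
        ok = (ppm_err <= config.ppm_max) & (np.abs(rt_err) <= config.annotation_rt_tol)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        best = idx[np.lexsort((np.abs(rt_err[idx]), ppm_err[idx]))[0]]
        entry = library.entries.iloc[best]
        out.append(
            Annotation(
                feature_id=str(fid),
                compound=str(entry["compound"]),
                enantiomer=str(entry["enantiomer"]),
                ppm_error=float(ppm_err[best]),
                rt_error=float(rt_err[best]),
            )
        )
    return out


def annotation_frame(
    table: FeatureTable, annotations: Sequence[Annotation]
) -> pd.DataFrame:
    """Per-feature annotation table; unmatched features are 'unknown'."""
    frame = pd.DataFrame(
        {
            "compound": "unknown",
            "enantiomer": "",
            "ppm_error": np.nan,
            "rt_error": np.nan,
        },
        index=table.features.index,
    )
    for ann in annotations:
        frame.loc[ann.feature_id, ["compound", "enantiomer", "ppm_error", "rt_error"]] = [
            ann.compound,
            ann.enantiomer,
            ann.ppm_error,
            ann.rt_error,
        ]
    return frame


def pairs_frame(pairs: Iterable[EnantiomerPair]) -> pd.DataFrame:
    """Serialize pairs for pairs.csv."""
    rows = [
        {
            "feature_a": p.feature_a,
            "feature_b": p.feature_b,
            "ppm_diff": p.ppm_diff,
            "rt_diff": p.rt_diff,
            "e1": p.e1,
            "e2": p.e2,
            "swap_status": p.swap_status,
            "gate_passed": p.gate_passed,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "feature_a",
            "feature_b",
            "ppm_diff",
            "rt_diff",
            "e1",
            "e2",
            "swap_status",
            "gate_passed",
        ],
    )
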