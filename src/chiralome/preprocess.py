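"""Probabilistic quotient normalization (PQN) and group summaries.

PQN corrects per-sample dilution: each sample's intensities are divided by
the median of its feature-wise quotients against a reference spectrum.  The
reference here is the per-feature median over the non-QC study samples; QC
pools are normalized with factors computed the same way against that same
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chiralome.io_formats import FeatureTable, GROUPS


class NormalizationError(RuntimeError):
    pass


@dataclass
class NormalizationReport:
    """Diagnostics from one PQN run."""

    reference: pd.Series            # per-feature reference intensity
    dilution_factor: pd.Series      # per-sample positive scalar
    n_features_used: pd.Series      # quotients entering each sample's median

    def __post_init__(self) -> None:
        if (self.dilution_factor <= 0).any():
            bad = self.dilution_factor.index[self.dilution_factor <= 0][0]
            raise NormalizationError(f"non-positive dilution factor for {bad!r}")
        if (self.n_features_used < 1).any():
            bad = self.n_features_used.index[self.n_features_used < 1][0]
            raise NormalizationError(f"no usable features for sample {bad!r}")

    def to_dict(self) -> dict:
        return {
            "dilution_factor": {k: float(v) for k, v in self.dilution_factor.items()},
            "n_features_used": {k: int(v) for k, v in self.n_features_used.items()},
        }


def pqn_normalize(
    table: FeatureTable, reference: pd.Series | None = None
) -> tuple[FeatureTable, NormalizationReport]:
    """Apply probabilistic quotient normalization to every sample.

    Reference = per-feature median over non-QC samples (missing skipped),
    unless an explicit ``reference`` series (indexed like the features) is
    supplied.  Per-sample quotients are taken over features non-missing in
    both the sample and the reference (zero-reference features skipped); the
    dilution factor is the median quotient and normalized intensity is
    raw / factor.

    Normalizing an already-normalized table against the *same* reference is
    the identity (all factors 1).  Re-deriving the median reference from the
    normalized table instead gives factors only statistically close to 1.

    Raises
    ------
    NormalizationError
        If fewer than two study samples exist or a sample shares no
        non-missing feature with the reference.
    """
    study = table.study_samples()
    if len(study) < 2:
        raise NormalizationError(
            f"PQN needs >= 2 non-QC samples, found {len(study)}"
        )
    inten = table.intensities
    if reference is None:
        reference = inten[study].median(axis=1, skipna=True)
    else:
        reference = reference.reindex(inten.index)
    usable_ref = reference.notna() & (reference > 0)

    factors: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for sample in inten.columns:
        col = inten[sample]
        mask = usable_ref & col.notna()
        n = int(mask.sum())
        if n == 0:
            raise NormalizationError(
                f"sample {sample!r} shares no non-missing feature with the reference"
            )
        quotients = col[mask] / reference[mask]
        factors[sample] = float(np.median(quotients))
        n_used[sample] = n

    factor_series = pd.Series(factors).reindex(inten.columns)
    normalized = inten.div(factor_series, axis=1)
    report = NormalizationReport(
        reference=reference,
        dilution_factor=factor_series,
        n_features_used=pd.Series(n_used).reindex(inten.columns),
    )
    return table.copy_with(normalized), report


def build_group_means(table: FeatureTable, group: str) -> pd.Series:
    """Per-feature arithmetic mean over the non-missing values of one group.

    Features with no non-missing value in the group get NaN.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    samples = table.group_samples(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    return table.intensities[samples].mean(axis=1, skipna=True)
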