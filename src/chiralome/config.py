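"""Analysis configuration: every threshold used by any stage lives here.

Nothing downstream hard-codes a cutoff; the config is echoed into the run
manifest so a result file is always traceable to the thresholds that
produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and switches for the full pipeline.

    Attributes
    ----------
    ppm_max : float
        Maximum m/z difference (ppm) for enantiomer pairing and annotation.
    rt_pair_max : float
        Maximum retention-time difference (minutes, strict) between the two
        members of a candidate enantiomer pair.
    annotation_rt_tol : float
        Retention-time tolerance (minutes) when matching features to the
        standards library; deliberately separate from ``rt_pair_max``.
    alpha : float
        Significance level for the 'significant' tier.
    borderline_hi : float
        Upper bound of the 'borderline' tier (``alpha <= p < borderline_hi``).
    fc_log2_threshold : float
        log2 fold-change magnitude used in feature-level reporting.
    fc_log2_absolute : bool
        Apply ``fc_log2_threshold`` to ``|log2_fc|`` (default) or signed.
    gene_fc_threshold : float
        Linear fold-change threshold for including a gene in the joint
        pathway analysis.
    gene_fc_absolute : bool
        If true (default) a gene passes when FC > threshold or
        FC < 1/threshold.
    cv_lo, cv_hi : float
        Open interval of acceptable per-gene coefficients of variation.
    r_min : float
        Minimum Pearson r for a gene-metabolite edge (positive correlations
        only).
    impact_min : float
        Topology-impact reporting cutoff for joint pathway results.
    p_combined_max : float
        Combined-p reporting cutoff for joint pathway results.
    swap_tau : float
        Minimum |log2| QC intensity ratio required (in both DATAN
        chiralities) before an elution-order swap is called verified.
    tail_mode : str
        'observed' (one-tailed in the empirical direction; p = two-tailed/2),
        'greater' or 'less' (fixed direction, positive vs negative group).
    equal_var : bool
        Pooled-variance Student t instead of Welch (default False = Welch).
    min_per_group : int
        Minimum non-missing values per group for a feature to be tested.
    seed : int
        Seed recorded in the manifest and used for any stochastic stage.
    """

    ppm_max: float = 5.0
    rt_pair_max: float = 3.0
    annotation_rt_tol: float = 1.0
    alpha: float = 0.05
    borderline_hi: float = 0.06
    fc_log2_threshold: float = 1.5
    fc_log2_absolute: bool = True
    gene_fc_threshold: float = 1.5
    gene_fc_absolute: bool = True
    cv_lo: float = 0.0
    cv_hi: float = 0.25
    r_min: float = 0.7
    impact_min: float = 0.2
    p_combined_max: float = 0.05
    swap_tau: float = 0.5
    tail_mode: str = "observed"
    equal_var: bool = False
    min_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < self.borderline_hi < 1.0):
            raise ValueError(
                "require 0 < alpha < borderline_hi < 1, got "
                f"alpha={self.alpha}, borderline_hi={self.borderline_hi}"
            )
        if self.ppm_max <= 0:
            raise ValueError(f"ppm_max must be > 0, got {self.ppm_max}")
        if self.rt_pair_max <= 0:
            raise ValueError(f"rt_pair_max must be > 0, got {self.rt_pair_max}")
        if not self.cv_lo < self.cv_hi:
            raise ValueError(
                f"require cv_lo < cv_hi, got {self.cv_lo} >= {self.cv_hi}"
            )
        if self.tail_mode not in ("observed", "greater", "less"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.min_per_group < 2:
            raise ValueError("min_per_group must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
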