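"""Synthetic data with machine-readable ground truth for every stage.

The generator emulates the structure of a small chiral-metabolomics study —
two groups of ~5 samples, thousands of log-normal features, planted
enantiomer pairs inside the pairing thresholds, planted group effects on the
log2 scale, (+)/(-)-agent QC pools with an exact intensity exchange inside
true pairs, and a TPM matrix with planted gene-metabolite correlations and
CV-banded background genes.  It is a testing stand-in, not a model of LC-MS
physics.

Modeling choices worth knowing:

* the two members of a planted pair share their per-sample noise and group
  effect, so the pair's intensity ratio is exactly ``2**log2_ratio`` in
  every sample — this is what makes QC swap verification exactly checkable;
* the plus-QC pool is the per-feature mean over all study samples (taken
  before missingness injection), and the minus-QC pool is the plus pool
  with intensities exchanged within every planted pair;
* missingness is injected completely at random into study samples only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chiralome.chiral_pairing import ppm_difference
from chiralome.io_formats import (
    ExpressionMatrix,
    FeatureTable,
    PathwayDefinition,
    StandardsLibrary,
)


def _params_echo(params) -> dict:
    """JSON-safe dataclass dump (tuples become lists, as in truth files)."""
    return json.loads(json.dumps(dataclasses.asdict(params)))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data.

    ``planted_pairs`` holds (feature_a, feature_b, log2_ratio) where
    feature_a is the planted low-abundance member (E1) and log2_ratio =
    log2(intensity_b / intensity_a) > 0.  ``planted_effects`` maps feature
    id to its true log2 fold change (positive over negative group).
    ``planted_edges`` holds (gene, metabolite, target_r).
    """

    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_effects: dict[str, float] = field(default_factory=dict)
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    planted_pathways: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [list(t) for t in self.planted_pairs],
            "planted_effects": self.planted_effects,
            "planted_edges": [list(t) for t in self.planted_edges],
            "planted_pathways": list(self.planted_pathways),
            "config_echo": self.config_echo,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_pairs=[tuple(t) for t in payload["planted_pairs"]],
            planted_effects=dict(payload["planted_effects"]),
            planted_edges=[tuple(t) for t in payload["planted_edges"]],
            planted_pathways=list(payload.get("planted_pathways", [])),
            config_echo=dict(payload["config_echo"]),
        )

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            planted_pairs=self.planted_pairs + other.planted_pairs,
            planted_effects={**self.planted_effects, **other.planted_effects},
            planted_edges=self.planted_edges + other.planted_edges,
            planted_pathways=self.planted_pathways + other.planted_pathways,
            config_echo={**self.config_echo, **other.config_echo},
        )


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTableParams:
    n_features: int = 500
    n_pairs: int = 100
    n_per_group: int = 5
    ppm_jitter_sd: float = 1.0          # ppm, per pair member
    ppm_max: float = 5.0                # pairs guaranteed inside this window
    rt_offset_range: tuple[float, float] = (0.2, 2.5)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_range: tuple[float, float] = (1.0, 20.0)
    log2_intensity_mean: float = 17.0
    log2_intensity_sd: float = 2.0
    pair_log2_ratio_range: tuple[float, float] = (0.5, 2.0)
    effect_fraction: float = 0.1
    effect_log2fc: float = 2.0
    noise_log2_sd: float = 0.5
    missing_fraction: float = 0.05
    seed: int = 42

    def validate(self) -> None:
        if 2 * self.n_pairs > self.n_features:
            raise ValueError(
                f"need n_features >= 2*n_pairs, got {self.n_features} < {2*self.n_pairs}"
            )
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        lo, hi = self.rt_offset_range
        if not 0.0 < lo <= hi:
            raise ValueError("rt_offset_range must be positive and ordered")
        if self.pair_log2_ratio_range[0] <= 0:
            raise ValueError("pair log2 ratios must be positive (E1 below E2)")


def generate_feature_table(
    params: FeatureTableParams | None = None,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate an aligned feature table with planted pairs and effects."""
    params = params or FeatureTableParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_pair_feat = 2 * params.n_pairs
    n_single = params.n_features - n_pair_feat
    n_entities = params.n_pairs + n_single
    npg = params.n_per_group
    study = [f"pos_{i+1}" for i in range(npg)] + [f"neg_{i+1}" for i in range(npg)]
    group_ind = np.array([1.0] * npg + [0.0] * npg)  # positive-group indicator

    width = len(str(params.n_features))
    fids = [f"F{i+1:0{width}d}" for i in range(params.n_features)]

    # entity-level draws
    entity_mass = rng.uniform(*params.mz_range, size=n_entities)
    entity_rt = rng.uniform(*params.rt_range, size=n_entities)
    entity_mu = rng.normal(
        params.log2_intensity_mean, params.log2_intensity_sd, size=n_entities
    )
    entity_noise = rng.normal(0.0, params.noise_log2_sd, size=(n_entities, 2 * npg))
    n_effect = int(round(params.effect_fraction * n_entities))
    effect_entities = rng.choice(n_entities, size=n_effect, replace=False)
    entity_effect = np.zeros(n_entities)
    entity_effect[effect_entities] = params.effect_log2fc

    mz = np.empty(params.n_features)
    rt = np.empty(params.n_features)
    log2_int = np.empty((params.n_features, 2 * npg))
    truth = SyntheticTruth(config_echo={"feature_table": _params_echo(params)})

    for e in range(params.n_pairs):
        ia, ib = 2 * e, 2 * e + 1  # feature row indices; a is planted E1
        while True:
            jit = rng.normal(0.0, params.ppm_jitter_sd, size=2)
            mz_a = entity_mass[e] * (1 + jit[0] * 1e-6)
            mz_b = entity_mass[e] * (1 + jit[1] * 1e-6)
            if ppm_difference(mz_a, mz_b) < params.ppm_max:
                break
        offset = rng.uniform(*params.rt_offset_range)
        if rng.random() < 0.5:  # either enantiomer may elute first
            rt_a, rt_b = entity_rt[e], entity_rt[e] + offset
        else:
            rt_a, rt_b = entity_rt[e] + offset, entity_rt[e]
        ratio = rng.uniform(*params.pair_log2_ratio_range)
        base = entity_mu[e] + entity_effect[e] * group_ind + entity_noise[e]
        mz[ia], mz[ib] = mz_a, mz_b
        rt[ia], rt[ib] = rt_a, rt_b
        log2_int[ia] = base - ratio  # E1: lower by the planted ratio
        log2_int[ib] = base
        truth.planted_pairs.append((fids[ia], fids[ib], float(ratio)))
        truth.planted_effects[fids[ia]] = float(entity_effect[e])
        truth.planted_effects[fids[ib]] = float(entity_effect[e])

    for s in range(n_single):
        e = params.n_pairs + s
        i = n_pair_feat + s
        mz[i] = entity_mass[e] * (1 + rng.normal(0.0, params.ppm_jitter_sd) * 1e-6)
        rt[i] = entity_rt[e]
        log2_int[i] = entity_mu[e] + entity_effect[e] * group_ind + entity_noise[e]
        truth.planted_effects[fids[i]] = float(entity_effect[e])

    intensities = np.power(2.0, log2_int)

    # QC pools from the complete (pre-missingness) matrix
    qc_plus = intensities.mean(axis=1)
    qc_minus = qc_plus.copy()
    for a, b, _ in truth.planted_pairs:
        ia, ib = fids.index(a), fids.index(b)
        qc_minus[ia], qc_minus[ib] = qc_plus[ib], qc_plus[ia]

    if params.missing_fraction > 0:
        mask = rng.random(intensities.shape) < params.missing_fraction
        intensities[mask] = np.nan

    inten = pd.DataFrame(intensities, index=pd.Index(fids, name="feature_id"),
                         columns=study)
    inten["QC_plus"] = qc_plus
    inten["QC_minus"] = qc_minus

    features = pd.DataFrame(
        {"mz": mz, "rt": rt}, index=pd.Index(fids, name="feature_id")
    )
    meta = pd.DataFrame(
        {
            "group": ["positive"] * npg + ["negative"] * npg + [np.nan, np.nan],
            "is_qc": [False] * (2 * npg) + [True, True],
            "datan_chirality": ["none"] * (2 * npg) + ["plus", "minus"],
        },
        index=pd.Index(study + ["QC_plus", "QC_minus"], name="sample"),
    )
    table = FeatureTable(features=features, intensities=inten, sample_meta=meta)
    return table, truth


def generate_standards(
    table: FeatureTable,
    truth: SyntheticTruth,
    n_chiral: int = 10,
    n_achiral: int = 5,
    seed: int = 0,
) -> StandardsLibrary:
    """Build a standards library whose entries match planted features.

    The first ``n_chiral`` planted pairs become D/L entries (D = the planted
    E1 feature's coordinates); ``n_achiral`` singleton features become
    achiral entries.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k, (fa, fb, _) in enumerate(truth.planted_pairs[:n_chiral]):
        name = f"compound_{k+1:03d}"
        for fid, en in ((fa, "D"), (fb, "L")):
            rows.append(
                {
                    "compound": name,
                    "enantiomer": en,
                    "expected_mz": float(table.features.loc[fid, "mz"]),
                    "expected_rt": float(table.features.loc[fid, "rt"]),
                }
            )
    paired = {f for fa, fb, _ in truth.planted_pairs for f in (fa, fb)}
    singles = [f for f in table.feature_ids if f not in paired]
    chosen = rng.choice(len(singles), size=min(n_achiral, len(singles)), replace=False)
    for k, idx in enumerate(sorted(chosen)):
        fid = singles[idx]
        rows.append(
            {
                "compound": f"achiral_{k+1:03d}",
                "enantiomer": "achiral",
                "expected_mz": float(table.features.loc[fid, "mz"]),
                "expected_rt": float(table.features.loc[fid, "rt"]),
            }
        )
    return StandardsLibrary(entries=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionParams:
    n_genes: int = 2000
    n_correlated_per_metabolite: int = 20
    target_r: float = 0.9
    noise_scale: float = 1.0            # 0 -> planted genes correlate exactly
    frac_in_cv_band: float = 0.5
    cv_band: tuple[float, float] = (0.05, 0.2)
    out_band_cv: tuple[float, float] = (0.3, 0.45)
    mean_tpm_range: tuple[float, float] = (50.0, 500.0)
    seed: int = 42

    def validate(self, n_metabolites: int) -> None:
        if not 0.0 < self.target_r < 1.0:
            raise ValueError(f"target_r must be in (0, 1), got {self.target_r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_correlated_per_metabolite * n_metabolites > self.n_genes:
            raise ValueError("not enough genes for the requested planted edges")
        if not 0.0 <= self.frac_in_cv_band <= 1.0:
            raise ValueError("frac_in_cv_band must be in [0, 1]")


def generate_expression(
    params: ExpressionParams,
    metabolite_abundances: pd.DataFrame,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a TPM matrix with planted gene-metabolite correlations.

    Planted genes are affine transforms of a metabolite vector plus Gaussian
    noise whose variance is calibrated so the expected Pearson r equals
    ``target_r``; background genes are independent with their realized CV
    pinned inside (or outside) the CV band.
    """
    n_mets = len(metabolite_abundances)
    params.validate(n_mets)
    rng = np.random.default_rng(params.seed)
    samples = list(metabolite_abundances.columns)
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 samples")

    genes: list[str] = []
    values = np.empty((params.n_genes, n))
    truth = SyntheticTruth(config_echo={"expression": _params_echo(params)})

    g = 0
    # planted correlated genes
    for met_name, met_vec in metabolite_abundances.iterrows():
        met = met_vec.to_numpy(dtype=float)
        sd_met = met.std(ddof=1)
        if sd_met == 0:
            raise ValueError(f"metabolite {met_name!r} has zero variance")
        for _ in range(params.n_correlated_per_metabolite):
            mean_tpm = rng.uniform(*params.mean_tpm_range)
            slope = 0.2 * mean_tpm / sd_met
            r = params.target_r
            sigma = params.noise_scale * slope * sd_met * np.sqrt(1.0 / r**2 - 1.0)
            vec = mean_tpm + slope * (met - met.mean()) + rng.normal(0, sigma, size=n)
            values[g] = np.clip(vec, 0.0, None)
            gene = f"PG{g+1:05d}"
            genes.append(gene)
            truth.planted_edges.append((gene, str(met_name), params.target_r))
            g += 1

    # background genes with controlled CV (z standardized so CV is exact)
    n_background = params.n_genes - g
    n_in_band = int(round(params.frac_in_cv_band * n_background))
    for b in range(n_background):
        mean_tpm = rng.uniform(*params.mean_tpm_range)
        band = params.cv_band if b < n_in_band else params.out_band_cv
        cv = rng.uniform(*band)
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        values[g] = mean_tpm * (1.0 + cv * z)
        genes.append(f"BG{g+1:05d}")
        g += 1

    tpm = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(tpm=tpm), truth


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


@dataclass
class PathwayParams:
    n_pathways: int = 5
    members_range: tuple[int, int] = (8, 16)
    planted_member_fraction: float = 0.8
    edge_probability: float = 0.3
    seed: int = 42


def generate_pathways(
    params: PathwayParams,
    gene_universe: list[str],
    cmpd_universe: list[str],
    planted_genes: list[str],
    planted_cmpds: list[str],
) -> tuple[list[PathwayDefinition], dict[str, list[tuple[str, str]]], SyntheticTruth]:
    """Random pathway sets; the first pathway over-samples planted members.

    Returns the definitions (topology attached), a topology edge-list
    mapping for serialization, and the truth naming the enriched pathway.
    """
    rng = np.random.default_rng(params.seed)
    truth = SyntheticTruth(config_echo={"pathways": _params_echo(params)})
    pathways: list[PathwayDefinition] = []
    topologies: dict[str, list[tuple[str, str]]] = {}

    def sample(pool: list[str], k: int) -> list[str]:
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in idx]

    for p in range(params.n_pathways):
        pid = f"PW{p+1:03d}"
        size = int(rng.integers(params.members_range[0], params.members_range[1] + 1))
        n_genes = max(1, int(round(size * 0.7)))
        n_cmpds = max(1, size - n_genes)
        if p == 0 and (planted_genes or planted_cmpds):
            n_pg = min(int(round(params.planted_member_fraction * n_genes)),
                       len(planted_genes))
            n_pc = min(int(round(params.planted_member_fraction * n_cmpds)),
                       len(planted_cmpds))
            g_members = set(sample(planted_genes, n_pg))
            c_members = set(sample(planted_cmpds, n_pc))
            g_members |= set(sample(
                [g for g in gene_universe if g not in g_members], n_genes - len(g_members)
            ))
            c_members |= set(sample(
                [c for c in cmpd_universe if c not in c_members], n_cmpds - len(c_members)
            ))
            truth.planted_pathways.append(pid)
        else:
            g_members = set(sample(gene_universe, n_genes))
            c_members = set(sample(cmpd_universe, n_cmpds))
        members = sorted(g_members | c_members)
        edges = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
            if rng.random() < params.edge_probability
        ]
        topologies[pid] = edges
        pathways.append(
            PathwayDefinition(
                pathway_id=pid,
                name=f"synthetic pathway {p+1}",
                gene_members=frozenset(g_members),
                compound_members=frozenset(c_members),
                topology=tuple(edges),
            )
        )
    return pathways, topologies, truth


# ---------------------------------------------------------------------------
# full preset
# ---------------------------------------------------------------------------


def write_preset(out_dir: str | Path, seed: int = 42) -> SyntheticTruth:
    """Write a complete paper-scale synthetic study to ``out_dir``.

    Produces features.tsv, samples.csv, standards.csv, expression.tsv,
    pathways.gmt, topology.tsv and truth.json.
    """
    from chiralome import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ft_params = FeatureTableParams(seed=seed)
    table, truth = generate_feature_table(ft_params)
    standards = generate_standards(table, truth, seed=seed + 1)

    # metabolite vectors for expression planting: positive-group abundances
    # of the first annotated planted-pair features
    pos = table.group_samples("positive")
    met_rows = {}
    for k, (fa, fb, _) in enumerate(truth.planted_pairs[:5]):
        met_rows[f"compound_{k+1:03d}|D"] = table.intensities.loc[fa, pos].fillna(
            table.intensities.loc[fa, pos].mean()
        )
    mets = pd.DataFrame(met_rows).T
    expr_params = ExpressionParams(seed=seed + 2)
    expr, expr_truth = generate_expression(expr_params, mets)
    truth = truth.merge(expr_truth)

    planted_gene_list = [g for g, _, _ in truth.planted_edges]
    planted_cmpd_list = sorted({m.split("|")[0] for _, m, _ in truth.planted_edges})
    cmpd_universe = sorted(set(standards.entries["compound"]))
    pathways, topologies, pw_truth = generate_pathways(
        PathwayParams(seed=seed + 3),
        gene_universe=list(expr.genes),
        cmpd_universe=cmpd_universe,
        planted_genes=planted_gene_list,
        planted_cmpds=planted_cmpd_list,
    )
    truth = truth.merge(pw_truth)

    io_formats.write_feature_table(table, out / "features.tsv", out / "samples.csv")
    io_formats.write_standards(standards, out / "standards.csv")
    io_formats.write_expression(expr, out / "expression.tsv")
    io_formats.write_gmt(pathways, out / "pathways.gmt")
    io_formats.write_topology(topologies, out / "topology.tsv")
    truth.to_json(out / "truth.json")
    return truth
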