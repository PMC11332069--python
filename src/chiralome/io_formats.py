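"""Readers, writers and validated in-memory types for all external artifacts.

Formats handled here:

* feature table — TSV, one row per aligned LC-MS feature (id, m/z, RT,
  per-sample intensities); MS-DIAL-style column aliases are recognised
* sample sheet — CSV mapping sample names to group / QC role / DATAN chirality
* standards library — CSV of (compound, enantiomer, expected m/z, expected RT)
* expression matrix — TSV, genes x samples, TPM
* pathway sets — GMT, optionally with a TSV edge list giving topology
* results — CSV tables plus a JSON run manifest
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from chiralome.config import AnalysisConfig

logger = logging.getLogger(__name__)

GROUPS = ("positive", "negative")
CHIRALITIES = ("plus", "minus", "none")

#: column-name aliases accepted for the three mandatory feature-table columns
FEATURE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "feature_id": ("feature_id", "Alignment ID", "alignment_id", "id"),
    "mz": ("mz", "m/z", "Average Mz", "average_mz"),
    "rt": ("rt", "RT", "rt_min", "Average Rt(min)", "average_rt"),
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Aligned LC-MS features with per-sample intensities and sample roles.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by feature id, columns ``mz`` (Th) and ``rt`` (minutes).
    intensities : pandas.DataFrame
        Features x samples; missing measurements are NaN.
    sample_meta : pandas.DataFrame
        Indexed by sample name, columns ``group`` ('positive'/'negative',
        NaN for QCs), ``is_qc`` (bool) and ``datan_chirality``
        ('plus'/'minus'/'none').
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        feats = self.features
        if feats.index.has_duplicates:
            dupes = feats.index[feats.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.intensities.columns.has_duplicates:
            dupes = self.intensities.columns[
                self.intensities.columns.duplicated()
            ].unique().tolist()
            raise ValidationError(f"duplicate sample names: {dupes[:5]}")
        bad_mz = feats.index[~(np.isfinite(feats["mz"]) & (feats["mz"] > 0))]
        if len(bad_mz):
            raise ValidationError(f"non-positive or non-finite mz for {bad_mz[0]!r}")
        bad_rt = feats.index[~(np.isfinite(feats["rt"]) & (feats["rt"] >= 0))]
        if len(bad_rt):
            raise ValidationError(f"negative or non-finite rt for {bad_rt[0]!r}")
        if not feats.index.equals(self.intensities.index):
            raise ValidationError("feature metadata and intensity rows differ")
        if set(self.intensities.columns) != set(self.sample_meta.index):
            raise ValidationError(
                "intensity columns and sample sheet entries do not match"
            )
        neg = self.intensities.lt(0)
        if neg.any().any():
            fid = self.intensities.index[neg.any(axis=1)][0]
            raise ValidationError(f"negative intensity for feature {fid!r}")
        for sample, row in self.sample_meta.iterrows():
            if row["is_qc"]:
                if row["datan_chirality"] not in ("plus", "minus"):
                    raise ValidationError(
                        f"QC sample {sample!r} needs a datan_chirality (plus/minus)"
                    )
            else:
                if row["group"] not in GROUPS:
                    raise ValidationError(
                        f"non-QC sample {sample!r} needs a group in {GROUPS}"
                    )

    # -- convenience accessors ---------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_names(self) -> pd.Index:
        return self.intensities.columns

    def study_samples(self) -> list[str]:
        """Non-QC sample names in column order."""
        meta = self.sample_meta
        keep = meta.index[~meta["is_qc"].astype(bool)]
        return [s for s in self.intensities.columns if s in set(keep)]

    def group_samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        meta = self.sample_meta
        keep = meta.index[(~meta["is_qc"].astype(bool)) & (meta["group"] == group)]
        return [s for s in self.intensities.columns if s in set(keep)]

    def qc_samples(self, chirality: str) -> list[str]:
        if chirality not in ("plus", "minus"):
            raise ValueError(f"unknown chirality {chirality!r}")
        meta = self.sample_meta
        keep = meta.index[
            meta["is_qc"].astype(bool) & (meta["datan_chirality"] == chirality)
        ]
        return [s for s in self.intensities.columns if s in set(keep)]

    def copy_with(self, intensities: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(
            features=self.features.copy(),
            intensities=intensities,
            sample_meta=self.sample_meta.copy(),
        )


@dataclass
class StandardsLibrary:
    """Reference compounds with expected m/z and RT per enantiomer entry."""

    entries: pd.DataFrame  # columns: compound, enantiomer, expected_mz, expected_rt

    VALID_ENANTIOMERS = ("D", "L", "E1", "E2", "achiral")

    def __post_init__(self) -> None:
        req = ["compound", "enantiomer", "expected_mz", "expected_rt"]
        missing = [c for c in req if c not in self.entries.columns]
        if missing:
            raise FormatError(f"standards library missing columns {missing}")
        ent = self.entries
        if (ent["expected_mz"] <= 0).any():
            bad = ent.loc[ent["expected_mz"] <= 0, "compound"].iloc[0]
            raise ValidationError(f"non-positive expected_mz for {bad!r}")
        bad_en = ~ent["enantiomer"].isin(self.VALID_ENANTIOMERS)
        if bad_en.any():
            raise ValidationError(
                f"unknown enantiomer label {ent.loc[bad_en, 'enantiomer'].iloc[0]!r}"
            )
        dup = ent.duplicated(subset=["compound", "enantiomer"])
        if dup.any():
            raise ValidationError(
                f"duplicate (compound, enantiomer) entry: "
                f"{tuple(ent.loc[dup, ['compound', 'enantiomer']].iloc[0])}"
            )
        counts = ent[ent["enantiomer"] != "achiral"].groupby("compound").size()
        too_many = counts[counts > 2]
        if len(too_many):
            raise ValidationError(
                f"compound {too_many.index[0]!r} has >2 enantiomer entries"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix."""

    tpm: pd.DataFrame  # index: gene symbols, columns: sample names

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            dupes = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        vals = self.tpm.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            gene = self.tpm.index[~np.isfinite(vals).all(axis=1)][0]
            raise ValidationError(f"non-finite TPM for gene {gene!r}")
        if (vals < 0).any():
            gene = self.tpm.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative TPM for gene {gene!r}")

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns


@dataclass
class PathwayDefinition:
    """A named set of gene and/or compound members with optional topology."""

    pathway_id: str
    name: str
    gene_members: frozenset[str] = frozenset()
    compound_members: frozenset[str] = frozenset()
    topology: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        self.gene_members = frozenset(self.gene_members)
        self.compound_members = frozenset(self.compound_members)
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id!r} has no members")
        if self.topology is not None:
            self.topology = tuple((str(a), str(b)) for a, b in self.topology)
            members = self.members
            for a, b in self.topology:
                if a not in members or b not in members:
                    raise ValidationError(
                        f"pathway {self.pathway_id!r} topology edge ({a!r}, {b!r}) "
                        "references a non-member"
                    )

    @property
    def members(self) -> frozenset[str]:
        return self.gene_members | self.compound_members


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------


def _resolve_columns(header: Iterable[str]) -> dict[str, str]:
    """Map canonical column names onto whatever aliases the file uses."""
    header = list(header)
    resolved: dict[str, str] = {}
    for canon, aliases in FEATURE_COLUMN_ALIASES.items():
        found = [h for h in header if h in aliases]
        if not found:
            raise FormatError(
                f"feature table is missing a {canon!r} column "
                f"(accepted names: {', '.join(aliases)})"
            )
        resolved[canon] = found[0]
    return resolved


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the CSV sample sheet (sample, group, is_qc, datan_chirality)."""
    sheet = pd.read_csv(path, dtype=str)
    required = ["sample", "group", "is_qc", "datan_chirality"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns {missing}")
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicate sample name {dup!r} in sample sheet")
    meta = sheet.set_index("sample")
    meta["is_qc"] = meta["is_qc"].str.strip().str.lower().isin(("1", "true", "yes"))
    meta["group"] = meta["group"].fillna("").str.strip().replace("", np.nan)
    meta["datan_chirality"] = (
        meta["datan_chirality"].fillna("none").str.strip().replace("", "none")
    )
    return meta[["group", "is_qc", "datan_chirality"]]


def read_feature_table(path: str | Path, sample_sheet: str | Path) -> FeatureTable:
    """Parse an aligned feature-table TSV together with its sample sheet.

    Unparseable intensity cells and zeros become missing (NaN); the paper's
    exports carry zero for unmeasured features and zero intensities are
    physically unmeasured.
    """
    meta = read_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(raw.columns)

    missing_samples = [s for s in meta.index if s not in raw.columns]
    if missing_samples:
        raise FormatError(
            f"feature table is missing sample columns {missing_samples} "
            "named in the sample sheet"
        )

    fid = raw[cols["feature_id"]].astype(str)
    if fid.duplicated().any():
        dup = fid[fid.duplicated()].iloc[0]
        raise ValidationError(f"duplicate feature id {dup!r}")
    features = pd.DataFrame(
        {
            "mz": pd.to_numeric(raw[cols["mz"]], errors="coerce"),
            "rt": pd.to_numeric(raw[cols["rt"]], errors="coerce"),
        }
    )
    features.index = pd.Index(fid, name="feature_id")

    inten = raw[list(meta.index)].apply(pd.to_numeric, errors="coerce")
    inten = inten.mask(inten == 0)  # zero == unmeasured
    inten.index = features.index

    table = FeatureTable(features=features, intensities=inten, sample_meta=meta)
    logger.info(
        "read feature table %s: %d features, %d samples (%d QC)",
        path,
        len(features),
        len(meta),
        int(meta["is_qc"].sum()),
    )
    return table


def write_feature_table(
    table: FeatureTable, path: str | Path, sample_sheet: str | Path
) -> None:
    """Write a feature table TSV and companion sample sheet CSV."""
    out = pd.DataFrame(
        {
            "feature_id": table.features.index,
            "mz": table.features["mz"].to_numpy(),
            "rt": table.features["rt"].to_numpy(),
        }
    )
    for sample in table.intensities.columns:
        out[sample] = table.intensities[sample].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")

    sheet = table.sample_meta.reset_index()
    sheet.columns = ["sample", "group", "is_qc", "datan_chirality"]
    sheet["group"] = sheet["group"].fillna("")
    sheet["is_qc"] = sheet["is_qc"].map({True: "true", False: "false"})
    sheet.to_csv(sample_sheet, index=False)


# ---------------------------------------------------------------------------
# standards / expression / pathways
# ---------------------------------------------------------------------------


def read_standards(path: str | Path) -> StandardsLibrary:
    """Read the standards-library CSV."""
    raw = pd.read_csv(path, dtype={"compound": str, "enantiomer": str})
    required = ["compound", "enantiomer", "expected_mz", "expected_rt"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"standards library {path} missing columns {missing}")
    raw["expected_mz"] = pd.to_numeric(raw["expected_mz"])
    raw["expected_rt"] = pd.to_numeric(raw["expected_rt"])
    return StandardsLibrary(entries=raw[required].copy())


def write_standards(library: StandardsLibrary, path: str | Path) -> None:
    library.entries.to_csv(path, index=False, float_format="%.17g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TPM TSV; first column holds gene symbols."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = "gene"
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric TPM value in {path}: {exc}") from exc
    return ExpressionMatrix(tpm=raw)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.tpm.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path, compound_prefix: str = "cpd:") -> list[PathwayDefinition]:
    """Read GMT pathway sets: ``id<TAB>description<TAB>member...`` per line.

    Members carrying ``compound_prefix`` are treated as compounds (prefix
    stripped); all other members are genes.
    """
    pathways: list[PathwayDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            pid, desc, *members = fields
            members = [m for m in members if m]
            genes = frozenset(m for m in members if not m.startswith(compound_prefix))
            cpds = frozenset(
                m[len(compound_prefix):] for m in members if m.startswith(compound_prefix)
            )
            pathways.append(
                PathwayDefinition(
                    pathway_id=pid, name=desc, gene_members=genes, compound_members=cpds
                )
            )
    return pathways


def write_gmt(
    pathways: Iterable[PathwayDefinition],
    path: str | Path,
    compound_prefix: str = "cpd:",
) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            members = sorted(pw.gene_members) + [
                compound_prefix + c for c in sorted(pw.compound_members)
            ]
            fh.write("\t".join([pw.pathway_id, pw.name, *members]) + "\n")


def read_topology(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a TSV edge list (pathway_id, node_a, node_b) grouped by pathway."""
    edges: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: topology line needs exactly 3 fields "
                    "(pathway_id, node_a, node_b)"
                )
            pid, a, b = fields
            edges.setdefault(pid, []).append((a, b))
    return edges


def write_topology(
    topologies: Mapping[str, Iterable[tuple[str, str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pid in topologies:
            for a, b in topologies[pid]:
                fh.write(f"{pid}\t{a}\t{b}\n")


def attach_topology(
    pathways: Iterable[PathwayDefinition],
    topologies: Mapping[str, Iterable[tuple[str, str]]],
) -> list[PathwayDefinition]:
    """Return pathway definitions with topology edges attached where given."""
    out = []
    for pw in pathways:
        topo = topologies.get(pw.pathway_id)
        out.append(
            PathwayDefinition(
                pathway_id=pw.pathway_id,
                name=pw.name,
                gene_members=pw.gene_members,
                compound_members=pw.compound_members,
                topology=tuple(topo) if topo is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# results / manifest
# ---------------------------------------------------------------------------


def write_manifest(
    path: str | Path,
    config: AnalysisConfig,
    seed: int | None = None,
    counts: Mapping[str, int] | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Write the JSON run manifest (config echo, seed, version, counts)."""
    from chiralome import __version__

    manifest = {
        "software_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed if seed is None else seed,
        "counts": dict(counts or {}),
        "p_values": "unadjusted (no multiple-testing correction applied)",
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_results(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result frame as ``<name>.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in results.items():
        target = out_dir / f"{name}.csv"
        frame.to_csv(target, index=False, float_format="%.17g")
        written.append(target)
    return written
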