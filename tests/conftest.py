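import numpy as np
import pandas as pd
import pytest

from chiralome.config import AnalysisConfig
from chiralome.io_formats import FeatureTable
from chiralome.synthetic_data import write_preset


@pytest.fixture
def config():
    return AnalysisConfig()


def make_table(mz, rt, intensities, groups=None, qc=None):
    """Build a FeatureTable from plain lists.

    intensities: dict sample -> list of per-feature values (NaN ok)
    groups: dict sample -> 'positive'/'negative' (default: all positive)
    qc: dict sample -> 'plus'/'minus' for QC pools
    """
    qc = qc or {}
    samples = list(intensities)
    groups = groups or {s: "positive" for s in samples if s not in qc}
    fids = [f"F{i+1}" for i in range(len(mz))]
    features = pd.DataFrame(
        {"mz": mz, "rt": rt}, index=pd.Index(fids, name="feature_id")
    )
    inten = pd.DataFrame(
        {s: np.asarray(v, dtype=float) for s, v in intensities.items()},
        index=features.index,
    )
    meta = pd.DataFrame(
        {
            "group": [groups.get(s, np.nan) for s in samples],
            "is_qc": [s in qc for s in samples],
            "datan_chirality": [qc.get(s, "none") for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return FeatureTable(features=features, intensities=inten, sample_meta=meta)


@pytest.fixture(scope="session")
def preset_dir(tmp_path_factory):
    """The default synthetic study (seed 42) written once per session."""
    out = tmp_path_factory.mktemp("preset")
    write_preset(out, seed=42)
    return out
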