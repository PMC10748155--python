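import numpy as np
import pandas as pd
import pytest

from cardiostack.config import ExperimentConfig
from cardiostack.folds import make_folds
from cardiostack.synthetic import DISEASES, MANIFEST_COLUMNS, CohortManifest, generate_cohort


@pytest.fixture(scope="session")
def tiny_cfg() -> ExperimentConfig:
    return ExperimentConfig.tiny(n_patients=40, seed=11)


@pytest.fixture(scope="session")
def as_cohort(tmp_path_factory, tiny_cfg):
    """40-patient tiny cohort with a strong planted AS signal, folds assigned."""
    root = tmp_path_factory.mktemp("as_cohort")
    manifest = generate_cohort(
        40,
        root,
        prevalences={
            "AS": (0.7, 0.0, 0.0, 0.3),
            "MR": (1.0, 0.0, 0.0, 0.0),
            "LVD": (1.0, 0.0, 0.0, 0.0),
        },
        seed=11,
        effect_size=1.0,
        page_width=tiny_cfg.page_width,
        page_height=tiny_cfg.page_height,
    )
    make_folds(manifest, seed=11)
    return manifest


def make_table_manifest(grades_by_disease: dict[str, list[str]]) -> CohortManifest:
    """Label-only manifest (no signal files) for fold/stacking tests."""
    n = len(next(iter(grades_by_disease.values())))
    rows = []
    for i in range(n):
        row = {
            "patient_id": f"P{i:04d}",
            "pcg_2RSB": "",
            "pcg_ERB": "",
            "pcg_APX": "",
            "ecg": "",
            "split": "",
            "fold": -1,
        }
        for d in DISEASES:
            row[f"{d}_grade"] = grades_by_disease.get(d, ["none"] * n)[i]
        rows.append(row)
    return CohortManifest(table=pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
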