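import numpy as np
import pandas as pd
import pytest

from statpgx import PairedExpressionSet, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Desk-sized study: enough genes/pairs for every funnel stage to bite."""
    return SimConfig(
        n_genes=300,
        n_lcl_pairs=60,
        n_hepatoma_pairs=7,
        n_liver_samples=20,
        pathway_size=10,
        seed=7,
    )


def make_paired_set(rng, n_genes=20, n_subjects=8, delta=None, covariates=None):
    """Hand-rolled paired statin/sham expression set for unit tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    sham = rng.normal(8, 1, (n_genes, n_subjects))
    if delta is None:
        delta = rng.normal(0, 0.5, (n_genes, n_subjects))
    statin = sham + delta
    statin_ids = [f"{s}_statin" for s in subjects]
    sham_ids = [f"{s}_sham" for s in subjects]
    intensities = pd.DataFrame(
        np.hstack([statin, sham]), index=genes, columns=statin_ids + sham_ids
    )
    pairing = pd.DataFrame(
        {"subject": subjects * 2, "exposure": ["statin"] * n_subjects + ["sham"] * n_subjects},
        index=statin_ids + sham_ids,
    )
    detection = pd.DataFrame(
        np.zeros((n_genes, 2 * n_subjects)), index=genes, columns=statin_ids + sham_ids
    )
    if covariates is None:
        covariates = pd.DataFrame(
            {"age": np.tile(rng.uniform(30, 60, n_subjects), 2)},
            index=statin_ids + sham_ids,
        )
    return PairedExpressionSet(
        intensities=intensities, detection_p=detection,
        pairing=pairing, covariates=covariates,
    )
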