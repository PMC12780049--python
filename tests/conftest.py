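import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import sparse

from spotfuse import synthetic as syn
from spotfuse.visium_io import VisiumDataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    return syn.default_truth(seed=0)


@pytest.fixture(scope="session")
def visium(truth):
    return syn.make_visium_fixture(truth=truth)


@pytest.fixture(scope="session")
def msi(truth, visium):
    # also populates truth.msi_bbox, needed by export_landmarks
    return syn.make_msi_fixture(truth=truth, visium=visium)


@pytest.fixture(scope="session")
def landmark_pool(truth, msi):
    return syn.export_landmarks(truth, n=20, jitter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("scenario") / "sc"
    syn.write_scenario(d, seed=0)
    return d


def toy_visium(
    counts: np.ndarray,
    gene_names: list[str] | None = None,
    spacing: float = 100.0,
) -> VisiumDataset:
    """Minimal hand-built VisiumDataset around a dense counts array."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    genes = gene_names or [f"G{i}" for i in range(n_genes)]
    barcodes = [f"BC-{i:02d}" for i in range(n_spots)]
    positions = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": np.arange(n_spots),
            "pxl_row_in_fullres": 50.0,
            "pxl_col_in_fullres": 50.0 + spacing * np.arange(n_spots),
        }
    ).set_index("barcode", drop=False)
    return VisiumDataset(
        barcodes=barcodes,
        features=pd.DataFrame(
            {"id": genes, "name": genes, "feature_type": "Gene Expression"}
        ),
        counts=sparse.csc_matrix(counts),
        positions=positions,
        scalefactors={
            "spot_diameter_fullres": 0.55 * spacing,
            "tissue_hires_scalef": 0.2,
            "tissue_lowres_scalef": 0.05,
        },
    ).validate()
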