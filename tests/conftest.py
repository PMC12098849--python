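import numpy as np
import pandas as pd
import pytest

from mirmsi import synthetic


@pytest.fixture(scope="session")
def two_class_phantom():
    """Ring of lipid-rich tissue inside protein background, light noise."""
    spec = synthetic.PhantomSpec(
        classes=(
            synthetic.protein_class("tissue"),
            synthetic.lipid_class("lipid_rich"),
        ),
        geometry=synthetic.GeometrySpec(
            background="tissue",
            rings=(synthetic.RingSpec("lipid_rich", 14.0, 26.0),),
        ),
        noise_sigma=0.02,
        seed=1,
    )
    return synthetic.make_mir_phantom(spec)


@pytest.fixture(scope="session")
def three_class_phantom():
    spec = synthetic.PhantomSpec(
        classes=(
            synthetic.protein_class("tissue"),
            synthetic.lipid_class("lipid_rich"),
            synthetic.sulfatide_class("sulfatide_rich"),
        ),
        geometry=synthetic.GeometrySpec(
            background="tissue",
            tissue_radius_frac=0.45,
            rings=(
                synthetic.RingSpec("lipid_rich", 12.0, 22.0),
                synthetic.RingSpec("sulfatide_rich", 26.0, 36.0),
            ),
        ),
        noise_sigma=0.02,
        seed=2,
    )
    return synthetic.make_mir_phantom(spec)


@pytest.fixture(scope="session")
def blob_phantom():
    """Ten planted circular blobs with high contrast over dim tissue."""
    spec = synthetic.PhantomSpec(
        shape=(128, 128),
        classes=(
            synthetic.protein_class("tissue", amplitude=0.3),
            synthetic.lipid_class("blob", amplitude=1.5),
        ),
        geometry=synthetic.GeometrySpec(
            background="tissue",
            tissue_radius_frac=0.48,
            blobs=(synthetic.BlobSpec(10, 5.6, "blob"),),
        ),
        noise_sigma=0.01,
        seed=3,
    )
    return synthetic.make_mir_phantom(spec)


@pytest.fixture()
def near_isobar_frame():
    """Discrete peak frame: SM4 38:2;O3 target, its M+1, and the
    SM4 39:1;O2 near-isobar 0.036 Da away but 0.029 Vs/cm^2 apart."""
    return pd.DataFrame({
        "x": 0, "y": 0,
        "mz": [848.556322, 849.559677, 848.592707],
        "intensity": [100.0, 48.0, 150.0],
        "inv_k0": [1.446, 1.446, 1.475],
    })


def random_peak_frame(rng: np.random.Generator, n_peaks: int = 15):
    """Random discrete peak list around a fixed target, for oracle checks."""
    target_mz = 848.556322
    mz = np.concatenate([[target_mz],
                         target_mz + rng.uniform(-2.0, 2.0, n_peaks)])
    intensity = np.concatenate([[100.0], rng.uniform(1.0, 300.0, n_peaks)])
    inv_k0 = np.concatenate([[1.446], 1.446 + rng.uniform(-0.02, 0.02, n_peaks)])
    return pd.DataFrame({"x": 0, "y": 0, "mz": mz, "intensity": intensity,
                         "inv_k0": inv_k0}), target_mz
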