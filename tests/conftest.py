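import numpy as np
import pytest

import feedcube as fc


@pytest.fixture(scope="session")
def sensor_grid():
    """The 275-band 894-2504 nm instrument grid."""
    return fc.make_grid(894.0, 2504.0, 275)


@pytest.fixture(scope="session")
def design_records():
    """Default five-group drying/rewetting design (200 samples)."""
    return fc.emulate_design(fc.DesignConfig())


@pytest.fixture(scope="session")
def spectra_table(sensor_grid, design_records):
    """Synthetic 200-sample spectra table restricted to 894-1917 nm."""
    y = np.array([100.0 * r.M_wb for r in design_records])
    X = fc.synth_spectra_matrix([r.M_wb for r in design_records], sensor_grid, seed=7)
    table = fc.SpectraTable(X, sensor_grid, y)
    return table.subset_bands(fc.subrange_indices(sensor_grid, 894.0, 1917.0))


@pytest.fixture()
def small_scene_cfg():
    """A small scene with a short grid for fast image tests."""
    return fc.SceneConfig(
        height=32, width=32, disk_radius=10, grid=fc.make_grid(894.0, 2504.0, 80), seed=11
    )


@pytest.fixture()
def noise_free_scene_cfg(small_scene_cfg):
    from dataclasses import replace

    return replace(small_scene_cfg, noise_floor=0.0)
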