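import numpy as np
import pytest

from rangeshift.pipeline import PipelineConfig, run_pipeline
from rangeshift.raster import GridTransform, RasterGrid
from rangeshift.synthetic import LandscapeConfig


def make_grid(values, west=72.0, north=39.0, cell=1.0 / 120.0, nodata=-9999.0, name="layer"):
    """Small geographic grid helper used across the suite."""
    return RasterGrid(
        np.asarray(values, dtype=float),
        GridTransform(west=west, north=north, dx=cell, dy=cell),
        nodata=nodata,
        name=name,
    )


@pytest.fixture(scope="session")
def mini_landscape():
    """A compact synthetic study system shared by read-only tests."""
    from rangeshift.synthetic import generate_landscape

    return generate_landscape(LandscapeConfig(shape=(100, 100), seed=7), n_occurrences=500)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One full pipeline run at compact scale, shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("mini_run")
    config = PipelineConfig(
        outdir=outdir,
        seed=7,
        landscape=LandscapeConfig(shape=(100, 100), seed=7),
        n_occurrences=500,
        n_background=2000,
        write_rasters=False,
    )
    return run_pipeline(config)
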