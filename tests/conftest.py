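import numpy as np
import pytest

from marbench.config import PRESETS
from marbench.projector import ProjectionGeometry
from marbench.study import ImagingPipeline


@pytest.fixture(scope="session")
def desk_pipeline() -> ImagingPipeline:
    """One calibrated desk-scale imaging pipeline shared by the suite."""
    return ImagingPipeline(PRESETS["desk"], lump_seed=0)


@pytest.fixture(scope="session")
def desk_geometry() -> ProjectionGeometry:
    return ProjectionGeometry(n_views=180, n_bins=185, fov=26.0)


@pytest.fixture(scope="session")
def fine_geometry() -> ProjectionGeometry:
    """Finer detector sampling for oracle comparisons."""
    return ProjectionGeometry(n_views=180, n_bins=513, fov=26.0)
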