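import numpy as np
import pytest

from swirf.spectra_io import CollectionDay, ScanSpectrum, WavelengthGrid

TINY_GRID = WavelengthGrid(start_nm=900.0, step_nm=3.5, n_points=3)


def make_scan(
    absorbance,
    specimen_id="m1",
    species="Sim sp. 1",
    day=CollectionDay.PRE,
    cycle=1,
    replicate=1,
    grid=None,
):
    absorbance = np.asarray(absorbance, dtype=float)
    if grid is None:
        grid = WavelengthGrid(start_nm=900.0, step_nm=3.5, n_points=absorbance.size)
    return ScanSpectrum(
        specimen_id=specimen_id,
        species=species,
        treatment_cycle=cycle,
        collection_day=day,
        scan_replicate=replicate,
        absorbance=absorbance,
        grid=grid,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)


@pytest.fixture
def tiny_scans():
    """Two specimens x two replicates on a 3-point grid."""
    return [
        make_scan([1.0, 2.0, 4.0], specimen_id="a", replicate=1),
        make_scan([1.1, 2.2, 4.4], specimen_id="a", replicate=2),
        make_scan([0.5, 1.5, 3.5], specimen_id="b", replicate=1),
        make_scan([0.6, 1.4, 3.6], specimen_id="b", replicate=2),
    ]


@pytest.fixture(scope="session")
def fixture_metadata():
    import warnings

    from swirf.spectra_io import load_fixture_metadata

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_fixture_metadata()


@pytest.fixture(scope="session")
def fixture_f():
    from swirf.spectra_io import load_fixture_f

    return load_fixture_f()
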