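import numpy as np
import pytest

from sstlab.mzml_io import RunData, SpectrumRecord
from sstlab.synthetic_data import default_sst_fixture, synth_dda_run, write_fixture


@pytest.fixture(scope="session")
def default_fixture_dir(tmp_path_factory):
    """Three healthy synthetic runs + queries.json + config.json on disk."""
    out = tmp_path_factory.mktemp("fixture_default")
    config_path = write_fixture(out, seed=11, variant="default", n_runs=3)
    return config_path


@pytest.fixture(scope="session")
def reversed_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_reversed")
    return write_fixture(out, seed=11, variant="reversed", n_runs=1)


@pytest.fixture(scope="session")
def shifted_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_shifted")
    return write_fixture(out, seed=11, variant="shifted", n_runs=1)


@pytest.fixture(scope="session")
def default_bundle():
    return default_sst_fixture(seed=11)


@pytest.fixture(scope="session")
def dda_runs(default_bundle):
    """Five in-memory DDA 'days' of the six-analyte panel."""
    from dataclasses import replace

    return [
        synth_dda_run(
            replace(default_bundle.generator, ms1_interval=0.05, seed=11 + i),
            f"day_{i + 1}",
        )
        for i in range(5)
    ]


def make_scan(
    scan_id="s1",
    ms_level=1,
    rt=1.0,
    peaks=((100.0, 10.0),),
    precursor_mz=None,
    activation="unknown",
    nce=None,
):
    peaks = sorted(peaks)
    return SpectrumRecord(
        scan_id=scan_id,
        ms_level=ms_level,
        rt_minutes=rt,
        mz_array=np.array([p[0] for p in peaks]),
        intensity_array=np.array([p[1] for p in peaks]),
        precursor_mz=precursor_mz,
        activation=activation,
        collision_energy=nce,
    )


def make_run(scans, run_id="testrun"):
    return RunData(run_id=run_id, scans=list(scans))
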