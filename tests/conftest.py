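import numpy as np
import pytest
from hypothesis import settings

from ovotools import regionquant as rq
from ovotools import synthgen as sg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nurse_phantom() -> sg.ChamberPhantom:
    """Zero-noise phantom with 4 well-separated nurse nuclei, no follicle shell.

    Isotropic 1-um voxels so voxelized volumes are directly comparable to
    analytic sphere volumes.
    """
    params = sg.ChamberPhantomParams(
        stage_or_age=40.0,
        voxel_size=(1.0, 0.5, 0.5),
        n_nurse_nuclei=4,
        nurse_nucleus_radius=5.0,
        include_follicle=False,
        noise_sd=0.0,
        seed=3,
    )
    return sg.simulate_chamber_stack(params)


@pytest.fixture(scope="session")
def full_phantom() -> sg.ChamberPhantom:
    """Zero-noise phantom with follicle shell and a 30% oocyte."""
    params = sg.ChamberPhantomParams(
        stage_or_age=48.0,
        voxel_size=(2.0, 1.0, 1.0),
        n_nurse_nuclei=5,
        nurse_nucleus_radius=5.0,
        oocyte_fraction=0.30,
        noise_sd=0.0,
        seed=2,
    )
    return sg.simulate_chamber_stack(params)


@pytest.fixture(scope="session")
def dumping_series() -> sg.DumpingSeries:
    """Zero-noise dumping time-lapse with default flow rates."""
    return sg.simulate_dumping_series(sg.DumpingFlowParams(seed=0))


@pytest.fixture(scope="session")
def dumping_region_series(dumping_series):
    """Normalized region time series quantified from the dumping phantom."""
    specs = [
        rq.RegionSpec("NCN"),
        rq.RegionSpec("NCC", roi_edge_px=6),
        rq.RegionSpec("AO", roi_edge_px=6),
        rq.RegionSpec("PO", roi_edge_px=6),
    ]
    ts = rq.region_timeseries(
        dumping_series.frames, specs, dumping_series.geometry, frame_stride=2
    )
    return ts.pivot(index="t_h", columns="region", values="normalized")
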