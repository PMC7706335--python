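import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hourly_temps():
    """Three full days of hourly records after a sowing date."""
    from mvgc.thermal_time import TemperatureSeries

    ts = pd.date_range("2019-03-02 00:00", periods=72, freq="h")
    temps = np.concatenate([
        np.full(24, 24.0),           # day 1: constant 24 °C
        np.full(24, -5.0),           # day 2: below base
        np.tile([12.0, -12.0], 12),  # day 3: half warm, half cold
    ])
    return TemperatureSeries(timestamps=ts, t_h=temps, sowing_date="2019-03-01")


@pytest.fixture
def nadir_view():
    from mvgc.plot_geometry import CameraView, nadir_rotation

    return CameraView(
        image_id="v0",
        position=[0.0, 0.0, 28.0],
        rotation=nadir_rotation(),
        focal_px=9000.0,
        principal_point=(3000.0, 2000.0),
        image_size=(6000, 4000),
        gsd_mm=3.0,
    )


@pytest.fixture
def square_plot():
    from mvgc.plot_geometry import PlotPolygon

    return PlotPolygon(
        plot_id="p1",
        corners=np.array(
            [[-0.75, -0.5, 0.0], [0.75, -0.5, 0.0], [0.75, 0.5, 0.0], [-0.75, 0.5, 0.0]]
        ),
        buffer_m=0.1,
        genotype="G01",
    )


@pytest.fixture
def two_level_image():
    """Half 0.2, half 0.8 multiview image (100 px) from the percentile example."""
    from mvgc.multiview_core import MultiviewImage

    vals = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)]).reshape(10, 10)
    return MultiviewImage(values=vals, n_views=10)
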