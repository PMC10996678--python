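import numpy as np
import pytest

from ignidyn.ignition import EventRaster, ParcelTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def sine_series():
    """Two-region series carrying a 0.05 Hz in-band and 0.15 Hz out-of-band tone."""
    tr = 3.0
    t = np.arange(400) * tr
    data = np.vstack([np.sin(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.15 * t)])
    return ParcelTimeSeries("sine", data, tr)


def raster_from_events(event_map: dict[int, list[int]], n_regions: int, n_time: int) -> EventRaster:
    """Build a raster from {region: [event TRs]} for hand-constructed cases."""
    ev = np.zeros((n_regions, n_time), dtype=np.uint8)
    for region, times in event_map.items():
        ev[region, times] = 1
    return EventRaster(events=ev, theta=1.0)
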