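import numpy as np
import pytest

from chronospeckle.timeseries import TimeSeries


@pytest.fixture
def grid_48h():
    """The two-day in vivo design: 2-h sampling for 48 h."""
    return 2.0 * np.arange(24)


@pytest.fixture
def cos12(grid_48h):
    """A sustained 12-h cosine on the 48-h design."""
    return TimeSeries(grid_48h, np.cos(2 * np.pi * grid_48h / 12.0))
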