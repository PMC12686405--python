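import numpy as np
import pytest

from nitrosip.kinetics import IncubationSeries
from nitrosip.sip import RoiIonCounts


@pytest.fixture
def perfect_series():
    """Noiseless line: 1/6 nM per hour -> 4.0 nM per day."""
    return IncubationSeries(
        region="test", station="S1", depth_m=10.0, treatment="NH4_15N",
        replicate="r1", time_h=np.array([0, 3, 6, 12, 24.0]),
        product_15N_nM=np.array([0, 0.5, 1.0, 2.0, 4.0]))


@pytest.fixture
def flat_series():
    return IncubationSeries(
        region="test", station="S1", depth_m=10.0, treatment="NH4_15N",
        replicate="r1", time_h=np.array([0, 3, 6, 12, 24.0]),
        product_15N_nM=np.ones(5))


def make_series(time_h, product, **kw):
    defaults = dict(region="test", station="S1", depth_m=10.0,
                    treatment="NH4_15N", replicate="r1")
    defaults.update(kw)
    return IncubationSeries(time_h=np.asarray(time_h, dtype=float),
                            product_15N_nM=np.asarray(product, dtype=float),
                            **defaults)


def make_roi(c14, c15, roi_id="roi1", group="other", treatment="NH4_15N"):
    return RoiIonCounts(roi_id=roi_id, group=group, treatment=treatment,
                        counts_14N=np.asarray(c14), counts_15N=np.asarray(c15))
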