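import numpy as np
import pytest

from pyoptode import CalibrationCurve, EnvironmentConditions

# Published per-disk calibration coefficients over 28 days of high-pH storage
# (disks a-c): Ksv then R0 by day.
HIGH_PH_KSV = {
    0: (0.012, 0.009, 0.010),
    7: (0.011, 0.010, 0.011),
    14: (0.011, 0.010, 0.011),
    28: (0.011, 0.010, 0.010),
}
HIGH_PH_R0 = {
    0: (1.881, 1.948, 1.930),
    7: (1.776, 1.875, 1.877),
    14: (1.727, 1.839, 1.825),
    28: (1.722, 1.828, 1.805),
}

# Published per-disk detection limits (% air saturation)
PER_DISK_LOD = (1.15, 0.58, 1.61)
PER_DISK_LOQ = (3.50, 1.75, 4.88)

# Published whole-tube permeabilities [mg/(min*bar)]
PERMEABILITY = {
    "plastic_centrifuge_50ml": 3.02e-3,
    "glass_voa_40ml": 1.75e-3,
    "double_ended_voa_40ml": 9.44e-4,
}


@pytest.fixture
def env21() -> EnvironmentConditions:
    return EnvironmentConditions(temperature_C=21.0, pressure_mbar=1013.0)


@pytest.fixture
def cal_larsen() -> CalibrationCurve:
    return CalibrationCurve(disk_id="d1", R0=1.9, Ksv=0.011, alpha=0.05)


def bisect_invert(R: float, R0: float, Ksv: float, alpha: float, hi: float = 1e7) -> float:
    """Independent inversion oracle: bisection on the forward response."""
    f = lambda C: R0 * (alpha + (1 - alpha) / (1 + Ksv * C)) - R
    lo, hi_ = 0.0, hi
    assert f(lo) >= 0 >= f(hi_)
    for _ in range(200):
        mid = 0.5 * (lo + hi_)
        if f(mid) >= 0:
            lo = mid
        else:
            hi_ = mid
    return 0.5 * (lo + hi_)
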