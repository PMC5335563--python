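import numpy as np
import pytest

from flavoquant import (
    NoiseSpec,
    TightBindingParams,
    TitrationProtocol,
    TwoTransitionFit,
    generate_titration,
)


@pytest.fixture
def protocol():
    """The standard titration schedule: 1.3 mL of 200 nM flavin, fifty
    5 uL additions of 5 uM apoenzyme."""
    return TitrationProtocol()


@pytest.fixture
def tight_params():
    """A tight binder (K_D = 18 nM) with strong quenching on binding."""
    return TightBindingParams(kd=18.0, f_flavin=1.0, f_complex=0.02, f_apo=0.01)


@pytest.fixture
def noiseless_series(tight_params, protocol):
    return generate_titration(tight_params, protocol, NoiseSpec(sigma=0.0))


@pytest.fixture
def two_step_melt_params():
    """Two-domain melt: MBP-like step at 55 C, thermostable domain at 90 C."""
    return TwoTransitionFit(baseline=0.0, amp1=1.0, amp2=1.0,
                            tm1=55.0, tm2=90.0, w1=2.0, w2=2.0)


def bisect_complex(ft: float, at: float, kd: float, iters: int = 200) -> float:
    """Independent mass-action equilibrium solver by bisection.

    Finds c in [0, min(ft, at)] with (ft - c)(at - c) = kd * c. The
    left side minus the right is monotonically decreasing on that
    interval, so plain bisection converges unconditionally.
    """
    lo, hi = 0.0, min(ft, at)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (ft - mid) * (at - mid) - kd * mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
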