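import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from lamline import preprocess as pp
from lamline import profiles as pr
from lamline import simulate as sim
from lamline.prf import PRFParams, ScreenGeometry


@pytest.fixture(scope="session")
def screen() -> ScreenGeometry:
    return ScreenGeometry(half_width=8.0, half_height=4.5, pixels_per_dva=20.0)


@pytest.fixture(scope="session")
def excitatory_prf() -> PRFParams:
    """Purely excitatory pRF (no normalization pool): closed forms available."""
    return PRFParams(x=0.0, y=0.0, sigma1=1.0, sigma2=1.0, amp_act=1.0, amp_norm=0.0)


@pytest.fixture(scope="session")
def suppressive_prf() -> PRFParams:
    """DN pRF with a broad normalization pool strong enough to dominate at
    large stimulus sizes (interior size-tuning peak, surround suppression)."""
    return PRFParams(
        x=1.0, y=0.5, sigma1=0.8, sigma2=2.4, amp_act=1.0, amp_norm=0.02, b=0.0, d=0.5
    )


@pytest.fixture(scope="session")
def noiseless_session():
    """One noiseless single-condition run per condition, plus sidecars.

    Single-condition runs keep the signal exactly separable into a laminar
    profile times a shared time course, which the round-trip checks rely on.
    """
    runs = {}
    for i, cond in enumerate(sim.CONDITIONS):
        paradigm = sim.single_condition_paradigm(cond, seed=10 + i)
        series, sidecar = sim.generate_session(
            paradigm, noise=sim.NoiseConfig.noiseless(), seed=0
        )
        runs[cond] = (series, sidecar, paradigm)
    return runs


@pytest.fixture(scope="session")
def noiseless_regridded(noiseless_session):
    """Per-condition regridded 20 x time evoked responses and the center
    template from the noiseless sessions."""
    tcs = {}
    tr = None
    for cond, (series, sidecar, paradigm) in noiseless_session.items():
        epochs = pp.preprocess_run(series, paradigm)
        tr = epochs.tr
        tcs[cond] = pp.select_gm_and_regrid(epochs.condition_mean(cond), series.gm_bounds)
    template = pr.build_template([tcs["center"]], tr=tr)
    return tcs, template, tr
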