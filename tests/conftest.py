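import numpy as np
import pytest

from metaphen import calorimetry as cal
from metaphen import synthetic_data as syn


def make_human_trace(ree=1440.0, rer=0.85, cog_gain=0.0, tef_gain=0.0,
                     dt=15.0, dur=1800.0, subject_id="S1"):
    """Three-period human trace with step responses confined to the
    steady-state buffer (constant plateaus inside every analysis window)."""
    t = np.arange(0.0, 3 * dur, dt)
    labels = np.where(t < dur, "rest",
                      np.where(t < 2 * dur, "cognitive", "glucose")).astype(object)
    vo2_rest = ree / (cal.WEIR_SCALE * (cal.WEIR_VO2 + cal.WEIR_VCO2 * rer))
    gain = np.ones_like(t)
    gain[labels == "cognitive"] = 1.0 + cog_gain
    gain[labels == "glucose"] = 1.0 + tef_gain
    return cal.GasExchangeTrace(
        subject_id=subject_id, species="human", time=t,
        vo2=vo2_rest * gain, vco2=rer * vo2_rest * gain,
        period_labels=labels)


@pytest.fixture
def flat_trace():
    return make_human_trace()


@pytest.fixture
def small_cohort():
    cfg = syn.CohortConfig(n_per_group=3, noise_sd=0.0, ree_effect=-150.0,
                           tef_gain=0.15, cog_gain=0.05, seed=11)
    return syn.gen_ic_cohort(cfg)


@pytest.fixture
def flux_plate():
    cfg = syn.FluxPlateConfig(wells_per_group=4, noise_sd=0.0, seed=7)
    return syn.gen_flux_plate(cfg)


@pytest.fixture
def count_matrix():
    cfg = syn.CountMatrixConfig(seed=21)
    return cfg, *syn.gen_count_matrix(cfg)
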