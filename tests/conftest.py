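import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ctsynergy import SimAgentConfig, SimComboConfig
from ctsynergy.assay import DosePoint, DoseResponseTable
from ctsynergy.median_effect import predict_fa, MedianEffectFit


def exact_table(dm: float, m: float, doses, condition="drug", ratio=0.0, time=72.0, clip_eps=0.005):
    """Noise-free dose-response table sampled from the median-effect model."""
    fit = MedianEffectFit(dm=dm, m=m)
    points = [DosePoint(0.0, (clip_eps,), clip_eps, excluded_from_fit=True)]
    for d in doses:
        fa = min(1 - clip_eps, max(clip_eps, predict_fa(fit, d)))
        points.append(DosePoint(d, (fa,), fa))
    return DoseResponseTable(condition=condition, ratio=ratio, time=time, points=tuple(points), clip_eps=clip_eps)


@pytest.fixture
def paper_dose_grid():
    return (0.01, 0.1, 1.0, 10.0, 100.0)


@pytest.fixture
def noise_free_pair():
    """Two noise-free single agents sharing a slope, for exact combination algebra.

    The shallow slope (m = 0.7) keeps every fa on the 0.01-100 uM grid
    inside the clip window, so noise-free fits are exact.
    """
    a1 = SimAgentConfig(name="drugA", dm=1.0, m=0.7, noise_sd=0.0, seed=11)
    a2 = SimAgentConfig(name="drugB", dm=0.5, m=0.7, noise_sd=0.0, seed=12)
    return a1, a2


def combo_config(a1, a2, psi=1.0, ratio=0.1, seed=13):
    return SimComboConfig(agent1=a1, agent2=a2, ratio=ratio, psi=psi, seed=seed)
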