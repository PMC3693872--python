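"""Seeded synthetic data with the statistical structure the pipeline assumes.

Two families of generators:

* MTT plates from median-effect ground truth — single agents with known
  (Dm, m) and constant-ratio combinations with a *tunable true combination
  index* psi: each combination dose's achieved effect is chosen so that the
  Loewe-style combination index equals psi at every point of the ray
  (psi = 1 reproduces additivity, psi < 1 synergism, psi > 1 antagonism).
  Fitting the simulated plates and recomputing the CI must therefore
  return psi up to fit error, which makes every pipeline stage verifiable
  at desk scale.

* Flow-cytometry event tables — annexin-V/PI bivariate log-normal mixtures
  (surviving / early apoptotic / late apoptotic) and DNA-content mixtures
  (Gaussian G1, Gaussian G2 at twice the G1 mean, broadened-uniform S
  phase in between) for the cytometry module.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ctsynergy.assay import AbsorbanceRecord
from ctsynergy.errors import SimulationConfigError

__all__ = [
    "SimAgentConfig",
    "SimComboConfig",
    "SimFlowConfig",
    "simulate_single_agent",
    "simulate_combination",
    "simulate_flow_events",
    "effective_dm",
    "combo_ground_truth_dm",
]

#: plate dose grid, uM (zero row = untreated control)
DEFAULT_DOSES = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)
#: readout times, hours
DEFAULT_TIMES = (0.0, 24.0, 48.0, 72.0)
#: simulated 650 nm reference level, OD
REFERENCE_OD = 0.05


@dataclass(frozen=True)
class SimAgentConfig:
    """Ground truth for one single-agent MTT experiment.

    ``dm``/``m`` are the median-effect parameters at the terminal (72 h)
    readout up to the potency-scaling factor; ``od_max`` the dynamic range
    of the corrected absorbance (untreated control level), ``od_bg`` a
    residual background that the 650 nm reference does *not* remove
    (0 by default: ratio normalization assumes background-free corrected
    OD); ``noise_sd`` the additive Gaussian OD noise; ``potency_half_time``
    shifts potency over time as ``Dm(t) = dm * (1 + half_time / t)`` so
    early readouts show weaker effects.
    """

    name: str = "drug1"
    dm: float = 10.0
    m: float = 1.0
    od_bg: float = 0.0
    od_max: float = 1.0
    noise_sd: float = 0.02
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 3
    times: tuple[float, ...] = DEFAULT_TIMES
    potency_half_time: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (self.dm > 0 and self.m > 0 and self.od_max > 0):
            raise SimulationConfigError("dm, m and od_max must be > 0")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimComboConfig:
    """Ground truth for a constant-ratio combination experiment.

    ``psi`` is the true combination index: the achieved effect at each
    compound-1 dose D solves ``D/Dx1(fa) + ratio*D/Dx2(fa) = psi``.
    Plate layout (doses, times, replicates, noise) is taken from
    ``agent1``.
    """

    agent1: SimAgentConfig = field(default_factory=lambda: SimAgentConfig(name="drug1"))
    agent2: SimAgentConfig = field(default_factory=lambda: SimAgentConfig(name="drug2"))
    ratio: float = 0.1
    psi: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.ratio > 0:
            raise SimulationConfigError("ratio must be > 0")
        if not (self.psi > 0 and math.isfinite(self.psi)):
            raise SimulationConfigError("psi must be finite and > 0")

    @property
    def condition(self) -> str:
        return f"combo:{self.agent1.name}+{self.agent2.name}"


@dataclass(frozen=True)
class SimFlowConfig:
    """Mixture settings for synthetic flow-cytometry events.

    ``fractions`` are the true component weights — (surviving, early, late)
    for annexin/PI, (G1, S, G2) for DNA content — and must sum to 1.
    ``locations`` / ``scales`` override the kind-specific defaults:
    log10-channel component means/sds for annexin/PI, or
    (g1_mean, g1_cv, g2_cv) for DNA content.
    """

    n_events: int = 20_000
    fractions: tuple[float, float, float] = (0.85, 0.05, 0.10)
    locations: tuple | None = None
    scales: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if any(f < 0 for f in self.fractions):
            raise SimulationConfigError("fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise SimulationConfigError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.n_events < 1:
            raise SimulationConfigError("n_events must be >= 1")


def effective_dm(config: SimAgentConfig, time: float) -> float:
    """Ground-truth median-effect dose at a readout time (inf at t = 0)."""
    if time <= 0:
        return math.inf
    return config.dm * (1.0 + config.potency_half_time / time)


def _fu_single(config: SimAgentConfig, dose: float, time: float) -> float:
    dm_t = effective_dm(config, time)
    if dose == 0 or math.isinf(dm_t):
        return 1.0
    return 1.0 / (1.0 + (dose / dm_t) ** config.m)


def _absorbance_rows(
    fu_of: "callable",
    condition: str,
    doses: tuple[float, ...],
    ratio: float,
    times: tuple[float, ...],
    replicates: int,
    od_bg: float,
    od_max: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[AbsorbanceRecord]:
    records = []
    for t in times:
        for i, dose in enumerate(doses):
            fu = fu_of(dose, t)
            for rep in range(1, replicates + 1):
                ref_noise = rng.normal(0.0, noise_sd / 5.0) if noise_sd > 0 else 0.0
                sig_noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                a650 = REFERENCE_OD + ref_noise
                a570 = REFERENCE_OD + od_bg + od_max * fu + sig_noise
                records.append(
                    AbsorbanceRecord(
                        well_id=f"{condition}-t{t:g}-d{i}-r{rep}",
                        condition=condition,
                        dose1=dose,
                        dose2=ratio * dose,
                        time=t,
                        a570=a570,
                        a650=a650,
                        replicate=rep,
                    )
                )
    return records


def simulate_single_agent(config: SimAgentConfig) -> list[AbsorbanceRecord]:
    """Simulate one single-agent plate series from median-effect ground truth.

    With ``noise_sd = 0`` the corrected OD is exactly
    ``od_bg + od_max * fu(D, t)``.
    """
    rng = np.random.default_rng(config.seed)
    return _absorbance_rows(
        lambda d, t: _fu_single(config, d, t),
        config.name,
        config.doses,
        0.0,
        config.times,
        config.replicates,
        config.od_bg,
        config.od_max,
        config.noise_sd,
        rng,
    )


def _solve_combo_fa(config: SimComboConfig, dose: float, time: float) -> float:
    """Effect level of the combination at compound-1 dose ``dose``.

    Solves CI(fa) = psi where
    CI(fa) = dose/Dx1(fa) + ratio*dose/Dx2(fa); the left side decreases
    monotonically from +inf (fa -> 0) to 0 (fa -> 1), so a root always
    exists in (0, 1).
    """
    a1, a2 = config.agent1, config.agent2
    dm1, dm2 = effective_dm(a1, time), effective_dm(a2, time)
    if dose == 0 or math.isinf(dm1):
        return 0.0

    def ci_minus_psi(fa: float) -> float:
        theta = fa / (1.0 - fa)
        dx1 = dm1 * theta ** (1.0 / a1.m)
        dx2 = dm2 * theta ** (1.0 / a2.m)
        return dose / dx1 + config.ratio * dose / dx2 - config.psi

    lo, hi = 1e-12, 1.0 - 1e-12
    flo, fhi = ci_minus_psi(lo), ci_minus_psi(hi)
    if not (flo > 0 > fhi):
        raise SimulationConfigError(
            f"cannot bracket the effect level at dose {dose} uM (psi={config.psi})"
        )
    return float(brentq(ci_minus_psi, lo, hi, xtol=1e-14, rtol=8.9e-16))


def simulate_combination(config: SimComboConfig) -> list[AbsorbanceRecord]:
    """Simulate a constant-ratio combination series with true CI = psi.

    The ground-truth combination index on the noise-free ray equals
    ``psi`` at every achieved effect level; when the agents share a slope
    m, the ray is itself exactly median-effect with
    ``Dm_c = psi / (1/Dm1 + ratio/Dm2)`` and the same m.
    """
    rng = np.random.default_rng(config.seed)
    a1 = config.agent1
    return _absorbance_rows(
        lambda d, t: 1.0 - _solve_combo_fa(config, d, t),
        config.condition,
        a1.doses,
        config.ratio,
        a1.times,
        a1.replicates,
        a1.od_bg,
        a1.od_max,
        a1.noise_sd,
        rng,
    )


def combo_ground_truth_dm(config: SimComboConfig, time: float = 72.0) -> float:
    """True compound-1-axis dose at which the combination reaches fa = 0.5.

    At fa = 0.5 both single-agent equieffective doses equal their Dm
    whatever the slopes, so the defining equation reduces to
    ``D * (1/Dm1 + ratio/Dm2) = psi`` exactly.
    """
    dm1 = effective_dm(config.agent1, time)
    dm2 = effective_dm(config.agent2, time)
    return config.psi / (1.0 / dm1 + config.ratio / dm2)


# -- flow cytometry ---------------------------------------------------------

#: log10-channel (annexin, PI) means per component: surviving, early, late
ANNEXIN_PI_LOCATIONS = ((1.8, 1.8), (3.0, 1.8), (3.0, 3.0))
ANNEXIN_PI_SCALE = 0.25
#: DNA content defaults: G1 mean (channel units), G1 CV, G2 CV
DNA_DEFAULTS = (50.0, 0.05, 0.04)


def simulate_flow_events(config: SimFlowConfig, kind: str = "annexin_pi") -> pd.DataFrame:
    """Draw one synthetic flow-cytometry event table.

    ``kind='annexin_pi'`` returns columns (event_id, annexin, pi): a
    three-component bivariate log-normal mixture — surviving cells low in
    both channels, early apoptotic annexin-high/PI-low, late apoptotic
    high in both.  ``kind='dna_content'`` returns (event_id, dna_content):
    Gaussian G1, Gaussian G2 centred at twice the G1 mean, and an S phase
    uniform between the two convolved with the G1 width.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    labels = rng.choice(3, size=n, p=np.asarray(config.fractions))
    if kind == "annexin_pi":
        locations = config.locations or ANNEXIN_PI_LOCATIONS
        scales = config.scales or (ANNEXIN_PI_SCALE,) * 3
        log_ann = np.empty(n)
        log_pi = np.empty(n)
        for k in range(3):
            mask = labels == k
            nk = int(mask.sum())
            log_ann[mask] = rng.normal(locations[k][0], scales[k], size=nk)
            log_pi[mask] = rng.normal(locations[k][1], scales[k], size=nk)
        return pd.DataFrame(
            {"event_id": np.arange(n), "annexin": 10.0**log_ann, "pi": 10.0**log_pi}
        )
    if kind == "dna_content":
        g1_mean, g1_cv, g2_cv = config.locations or DNA_DEFAULTS
        g1_sd = g1_mean * g1_cv
        g2_sd = 2.0 * g1_mean * g2_cv
        x = np.empty(n)
        for k, sampler in enumerate(
            (
                lambda nk: rng.normal(g1_mean, g1_sd, size=nk),
                lambda nk: rng.uniform(g1_mean, 2.0 * g1_mean, size=nk)
                + rng.normal(0.0, g1_sd, size=nk),
                lambda nk: rng.normal(2.0 * g1_mean, g2_sd, size=nk),
            )
        ):
            mask = labels == k
            x[mask] = sampler(int(mask.sum()))
        return pd.DataFrame({"event_id": np.arange(n), "dna_content": x})
    raise ValueError(f"unknown event kind: {kind!r}")
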