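"""Flow-cytometry summaries: annexin-V/PI quadrant gating and DNA-content
cell-cycle deconvolution.

Quadrant gating classifies each event by two explicit intensity cuts:
surviving = annexin-/PI-, early apoptotic = annexin+/PI-, late apoptotic =
annexin+/PI+, and the residual annexin-/PI+ quadrant is reported as
"other" (mechanically damaged / necrotic).  Events exactly on a cut are
assigned to the positive side.

Cell-cycle analysis fits a three-component mixture to DNA content: a
Gaussian G1 peak at mean c, a Gaussian G2/M peak constrained to mean 2c
(DNA doubling), and an S phase modeled as a uniform distribution between
c and 2c convolved with the G1 width — a Dean-Jett-Fox-style
simplification identifiable at desk scale.  Fractions are posterior
component masses from an EM fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ctsynergy.errors import CellCycleConvergenceError

__all__ = [
    "QuadrantThresholds",
    "QuadrantSummary",
    "CellCycleSummary",
    "gate_quadrants",
    "fit_cell_cycle",
]


@dataclass(frozen=True)
class QuadrantThresholds:
    """Channel cuts separating negative from positive events (linear scale)."""

    annexin_cut: float
    pi_cut: float

    def __post_init__(self):
        if not (self.annexin_cut > 0 and np.isfinite(self.annexin_cut)):
            raise ValueError("annexin_cut must be finite and > 0")
        if not (self.pi_cut > 0 and np.isfinite(self.pi_cut)):
            raise ValueError("pi_cut must be finite and > 0")


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant percentages; they sum to 100 by construction."""

    pct_surviving: float
    pct_early: float
    pct_late: float
    pct_other: float

    def to_row(self) -> dict:
        return {
            "pct_surviving": self.pct_surviving,
            "pct_early": self.pct_early,
            "pct_late": self.pct_late,
            "pct_other": self.pct_other,
        }


@dataclass(frozen=True)
class CellCycleSummary:
    """Cell-cycle phase percentages with the fitted mixture parameters.

    ``g2_mean`` is always exactly ``2 * g1_mean`` (model constraint).
    ``log_likelihoods`` is the per-iteration trajectory of the observed
    log-likelihood; it is nondecreasing.
    """

    pct_g1: float
    pct_s: float
    pct_g2: float
    g1_mean: float
    g1_sd: float
    g2_sd: float
    n_iter: int
    log_likelihoods: tuple[float, ...]
    converged: bool

    @property
    def g2_mean(self) -> float:
        return 2.0 * self.g1_mean

    def to_row(self) -> dict:
        return {"pct_g1": self.pct_g1, "pct_s": self.pct_s, "pct_g2": self.pct_g2}


def gate_quadrants(events: pd.DataFrame, thresholds: QuadrantThresholds) -> QuadrantSummary:
    """Quadrant percentages from an annexin/PI event table.

    ``events`` needs columns ``annexin`` and ``pi`` (linear intensities).
    Order-invariant; an event exactly at a cut counts as positive.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    ann_pos = events["annexin"].to_numpy() >= thresholds.annexin_cut
    pi_pos = events["pi"].to_numpy() >= thresholds.pi_cut
    n = len(events)
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / n
    return QuadrantSummary(
        pct_surviving=pct(~ann_pos & ~pi_pos),
        pct_early=pct(ann_pos & ~pi_pos),
        pct_late=pct(ann_pos & pi_pos),
        pct_other=pct(~ann_pos & pi_pos),
    )


def _component_densities(x: np.ndarray, c: float, s1: float, s2: float) -> np.ndarray:
    """(n, 3) densities: G1 Gaussian, S broadened uniform, G2 Gaussian."""
    f_g1 = norm.pdf(x, c, s1)
    # uniform on (c, 2c) convolved with N(0, s1): difference of normal CDFs / width
    f_s = (norm.cdf((x - c) / s1) - norm.cdf((x - 2.0 * c) / s1)) / c
    f_g2 = norm.pdf(x, 2.0 * c, s2)
    return np.column_stack([f_g1, f_s, f_g2])


def _log_likelihood(x: np.ndarray, w: np.ndarray, c: float, s1: float, s2: float) -> float:
    mix = _component_densities(x, c, s1, s2) @ w
    return float(np.log(np.maximum(mix, 1e-300)).sum())


def fit_cell_cycle(
    dna_content,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CellCycleSummary:
    """Deconvolve a DNA-content distribution into G1/S/G2 fractions by EM.

    Initialization: the G1 mean starts at the histogram mode (the G2 mean
    is tied to twice it), widths at 6% CV, equal weights.  Each iteration
    performs the exact EM update for the mixture weights, then a
    safeguarded update of (c, s1, s2): closed-form candidates from the
    Gaussian responsibilities, accepted only after a backtracking check
    that the observed log-likelihood does not decrease (the S component's
    density depends on c and s1, so the naive closed form alone is not an
    EM step).  This keeps the log-likelihood trajectory nondecreasing.

    Raises
    ------
    CellCycleConvergenceError
        if the log-likelihood gain is still above ``tol`` after
        ``max_iter`` iterations; the exception carries the last iterate.
    """
    x = np.asarray(dna_content, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite DNA-content events")

    # histogram-mode initialization
    counts, edges = np.histogram(x, bins=128)
    c = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    s1 = max(0.06 * c, 1e-6)
    s2 = max(0.12 * c, 1e-6)
    w = np.array([1 / 3, 1 / 3, 1 / 3])

    ll = _log_likelihood(x, w, c, s1, s2)
    trajectory = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        dens = _component_densities(x, c, s1, s2)
        weighted = dens * w
        total = np.maximum(weighted.sum(axis=1, keepdims=True), 1e-300)
        gamma = weighted / total

        # exact M-step for the weights (never decreases the likelihood)
        w = gamma.mean(axis=0)
        w = np.maximum(w, 1e-12)
        w = w / w.sum()

        # closed-form candidates for (c, s1, s2) from the Gaussian components
        g1, g2 = gamma[:, 0], gamma[:, 2]
        n1, n2 = g1.sum(), g2.sum()
        denom = n1 / s1**2 + 4.0 * n2 / s2**2
        c_new = ((g1 @ x) / s1**2 + 2.0 * (g2 @ x) / s2**2) / denom if denom > 0 else c
        s1_new = np.sqrt(max((g1 @ (x - c_new) ** 2) / n1, 1e-12)) if n1 > 1e-9 else s1
        s2_new = np.sqrt(max((g2 @ (x - 2.0 * c_new) ** 2) / n2, 1e-12)) if n2 > 1e-9 else s2

        # backtracking safeguard: shrink the step toward the current iterate
        # until the observed log-likelihood does not decrease
        ll_w = _log_likelihood(x, w, c, s1, s2)
        step = 1.0
        ll_new = ll_w
        for _ in range(20):
            cand = (
                c + step * (c_new - c),
                s1 + step * (s1_new - s1),
                s2 + step * (s2_new - s2),
            )
            ll_cand = _log_likelihood(x, w, *cand)
            if ll_cand >= ll_w - 1e-12:
                c, s1, s2 = cand
                ll_new = ll_cand
                break
            step *= 0.5
        trajectory.append(ll_new)
        if ll_new - ll < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    pct = 100.0 * w
    summary = CellCycleSummary(
        pct_g1=float(pct[0]),
        pct_s=float(pct[1]),
        pct_g2=float(pct[2]),
        g1_mean=float(c),
        g1_sd=float(s1),
        g2_sd=float(s2),
        n_iter=len(trajectory) - 1,
        log_likelihoods=tuple(trajectory),
        converged=converged,
    )
    if not converged:
        raise CellCycleConvergenceError(summary, max_iter)
    return summary
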