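"""Chou-Talalay combination-index analysis for constant-ratio designs.

A constant-ratio (ray) experiment doses two compounds at a fixed ratio
``r = dose2 / dose1`` while the total dose scales.  With single-agent
median-effect fits for each compound and a median-effect fit of the
combination on the compound-1 dose axis, the combination index at effect
level ``fa`` is the two-term (mutually exclusive) form::

    CI(fa) = D1 / Dx1(fa) + D2 / Dx2(fa)

where ``D1 = Dx_combo(fa)`` is the compound-1 dose of the combination
producing fa, ``D2 = r * D1``, and ``Dx_i(fa)`` the dose of compound ``i``
alone producing the same effect.  CI < 1 indicates synergism, CI = 1
additivity (the Loewe reference), CI > 1 antagonism.  At fa = 0.5 the
expression reduces to ``CI = Dm_c/Dm_1 + r * Dm_c/Dm_2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from ctsynergy.assay import AbsorbanceRecord, build_dose_response, DEFAULT_CLIP_EPS
from ctsynergy.errors import CTSynergyError, MissingSeriesError
from ctsynergy.median_effect import MedianEffectFit, dose_for_effect, fit_median_effect

__all__ = [
    "RayDesign",
    "CombinationAnalysis",
    "ci_at_fa",
    "classify_ci",
    "ci_curve",
    "dose_reduction_index",
    "analyze_combination",
    "combo_condition_label",
]

Classification = Literal["synergism", "additive", "antagonism"]


@dataclass(frozen=True)
class RayDesign:
    """Constant-ratio design: compound 2 dosed at ``ratio`` times compound 1."""

    compound1: str
    compound2: str
    ratio: float = 0.1

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError(f"ratio must be > 0, got {self.ratio}")


@dataclass(frozen=True)
class CombinationAnalysis:
    """Bundle of single-agent fits, combination fit and the CI verdict."""

    fit1: MedianEffectFit
    fit2: MedianEffectFit
    fit_combo: MedianEffectFit
    design: RayDesign
    ci: float
    reference_fa: float
    classification: Classification

    def to_row(self, cell_line: str = "") -> dict:
        """One results row mirroring the conventional summary-table columns."""
        return {
            "cell_line": cell_line,
            "compound1": self.design.compound1,
            "compound2": self.design.compound2,
            "ic50_uM": self.fit_combo.dm,
            "m": self.fit_combo.m,
            "ci": self.ci,
            "r2": self.fit_combo.r2,
        }


def combo_condition_label(compound1: str, compound2: str) -> str:
    """Default condition label for a combination series."""
    return f"combo:{compound1}+{compound2}"


def ci_at_fa(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: RayDesign,
    fa: float = 0.5,
) -> float:
    """Two-term combination index at effect level ``fa``."""
    d1 = dose_for_effect(fit_combo, fa)
    d2 = design.ratio * d1
    ci = d1 / dose_for_effect(fit1, fa) + d2 / dose_for_effect(fit2, fa)
    if not math.isfinite(ci):
        raise CTSynergyError(f"non-finite CI at fa={fa}")
    return ci


def classify_ci(ci: float, band: float = 0.0) -> Classification:
    """Classify an interaction from its CI.

    With the default band of 0 the strict inequalities apply: CI < 1
    synergism, CI > 1 antagonism, CI = 1 additive.  A positive ``band``
    widens the additive verdict to ``[1 - band, 1 + band]``.
    """
    if not ci > 0:
        raise ValueError(f"ci must be > 0, got {ci}")
    if band < 0:
        raise ValueError("band must be >= 0")
    if ci < 1.0 - band:
        return "synergism"
    if ci > 1.0 + band:
        return "antagonism"
    return "additive"


def ci_curve(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: RayDesign,
    fa_grid: Sequence[float],
) -> pd.DataFrame:
    """Combination index over a grid of effect levels (the fa-CI curve)."""
    rows = [(fa, ci_at_fa(fit1, fit2, fit_combo, design, fa)) for fa in fa_grid]
    return pd.DataFrame(rows, columns=["fa", "ci"])


def dose_reduction_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: RayDesign,
    fa: float = 0.5,
) -> tuple[float, float]:
    """Fold dose reduction of each compound in combination at effect ``fa``.

    ``DRI_i = Dx_i(fa) / D_i`` with the combination doses as in
    :func:`ci_at_fa`; the identity ``CI = 1/DRI1 + 1/DRI2`` holds exactly.
    """
    d1 = dose_for_effect(fit_combo, fa)
    d2 = design.ratio * d1
    return dose_for_effect(fit1, fa) / d1, dose_for_effect(fit2, fa) / d2


def analyze_combination(
    records: Sequence[AbsorbanceRecord],
    design: RayDesign,
    *,
    combo_condition: str | None = None,
    time: float = 72.0,
    reference_fa: float = 0.5,
    clip_eps: float = DEFAULT_CLIP_EPS,
    pooling: str = "pooled-replicates",
    refine: bool = False,
    classification_band: float = 0.0,
) -> CombinationAnalysis:
    """Run the full pipeline on raw plate records.

    Builds dose-response tables for both single agents and the combination
    series at the requested time, fits the median-effect line to each,
    and evaluates the CI at ``reference_fa`` (0.5 = the IC50 level, the
    conventional reporting point).

    Raises
    ------
    MissingSeriesError
        if any of the three series has no wells at the requested time.
    """
    combo_condition = combo_condition or combo_condition_label(design.compound1, design.compound2)
    conditions = {r.condition for r in records if r.time == time}
    fits = {}
    tables = {}
    for label in (design.compound1, design.compound2, combo_condition):
        if label not in conditions:
            raise MissingSeriesError(label)
        tables[label] = build_dose_response(records, label, time, clip_eps=clip_eps)
        fits[label] = fit_median_effect(tables[label], pooling=pooling, refine=refine)
    combo_table_ratio = tables[combo_condition].ratio
    if combo_table_ratio and abs(combo_table_ratio - design.ratio) > 1e-9 * design.ratio:
        raise CTSynergyError(
            f"design ratio {design.ratio} does not match the ratio {combo_table_ratio} "
            f"found in series {combo_condition!r}"
        )
    ci = ci_at_fa(fits[design.compound1], fits[design.compound2], fits[combo_condition], design, reference_fa)
    return CombinationAnalysis(
        fit1=fits[design.compound1],
        fit2=fits[design.compound2],
        fit_combo=fits[combo_condition],
        design=design,
        ci=ci,
        reference_fa=reference_fa,
        classification=classify_ci(ci, classification_band),
    )
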