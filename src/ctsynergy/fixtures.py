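"""Packaged summary-table fixture of published median-effect fits.

The fixture transcribes two published summary tables of MTT experiments
in rhabdoid tumor cell lines (A204, G401, BT16): single-agent
median-effect fits (IC50 = Dm, slope m, R²) for HDAC inhibitors (SAHA,
TSA, M344), cyclin-D inhibitors (4-OH-tamoxifen "Tam", fenretinide
"Fen") and doxorubicin ("DOXO"), plus 13 constant-ratio (1:10)
combination rows with their reported CI at fa = 0.5.

Because the raw plates behind those tables are not published, the
consistency check recomputes each combination's CI from the *printed*
single-agent (IC50, m) and combined IC50 under the 1:10 design and
compares it with the printed CI.  Two rows are known to disagree beyond
rounding (the published CIs were presumably computed from unrounded
fits); they are flagged, never dropped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ctsynergy.combination import ci_at_fa, RayDesign
from ctsynergy.median_effect import MedianEffectFit

__all__ = ["load_printed_tables", "check_fixture", "DEFAULT_RATIO"]

#: the published constant-ratio design: compound 2 at 1/10 of compound 1
DEFAULT_RATIO = 0.1


def load_printed_tables() -> pd.DataFrame:
    """Load the packaged fixture.

    Returns a frame with columns ``table, cell_line, compound1, compound2,
    ic50_uM, m, ci, r2``; single-agent rows have empty ``compound2`` and
    missing ``ci``.
    """
    frames = []
    for name in ("table1", "table2"):
        with resources.files("ctsynergy.data").joinpath(f"{name}.csv").open() as fh:
            df = pd.read_csv(fh, dtype={"compound2": "string"})
        df.insert(0, "table", name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["compound2"] = out["compound2"].fillna("")
    return out


def _single_agent_fit(table: pd.DataFrame, cell_line: str, compound: str) -> MedianEffectFit:
    rows = table[
        (table["cell_line"] == cell_line)
        & (table["compound1"] == compound)
        & (table["compound2"] == "")
    ]
    if rows.empty:
        raise KeyError(f"no single-agent row for {compound} in {cell_line}")
    row = rows.iloc[0]
    return MedianEffectFit(dm=float(row["ic50_uM"]), m=float(row["m"]), r2=float(row["r2"]))


def check_fixture(ratio: float = DEFAULT_RATIO, tol: float = 0.02, fa: float = 0.5) -> pd.DataFrame:
    """Recompute every combination row's CI from printed parameters.

    For each of the 13 combination rows the CI at ``fa`` is recomputed
    from the printed single-agent (IC50, m) fits of the same table and
    cell line and the printed combined IC50 under ``dose2 = ratio *
    dose1``.  Returns one row per combination with columns ``cell_line,
    compound1, compound2, ci_printed, ci_recomputed, abs_delta, ok``
    where ``ok`` is ``|delta| <= tol``.
    """
    fixture = load_printed_tables()
    rows = []
    for tbl_name, tbl in fixture.groupby("table", sort=True):
        combos = tbl[tbl["compound2"] != ""]
        for _, row in combos.iterrows():
            fit1 = _single_agent_fit(tbl, row["cell_line"], row["compound1"])
            fit2 = _single_agent_fit(tbl, row["cell_line"], row["compound2"])
            fit_combo = MedianEffectFit(dm=float(row["ic50_uM"]), m=float(row["m"]), r2=float(row["r2"]))
            design = RayDesign(row["compound1"], row["compound2"], ratio)
            ci = ci_at_fa(fit1, fit2, fit_combo, design, fa)
            printed = float(row["ci"])
            rows.append(
                {
                    "table": tbl_name,
                    "cell_line": row["cell_line"],
                    "compound1": row["compound1"],
                    "compound2": row["compound2"],
                    "ci_printed": printed,
                    "ci_recomputed": ci,
                    "abs_delta": abs(ci - printed),
                    "ok": abs(ci - printed) <= tol,
                }
            )
    return pd.DataFrame(rows)
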