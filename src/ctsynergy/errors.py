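"""Exception hierarchy shared across the pipeline."""


class CTSynergyError(Exception):
    """Base class for all package errors."""


class PlateSchemaError(CTSynergyError):
    """A required column is missing from a plate table."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"plate table is missing required column(s): {', '.join(self.missing)}")


class PlateParseError(CTSynergyError):
    """One or more data rows could not be parsed."""

    def __init__(self, bad_rows: list[tuple[int, str]]):
        self.bad_rows = list(bad_rows)
        detail = "; ".join(f"row {i}: {msg}" for i, msg in self.bad_rows)
        super().__init__(f"malformed plate rows: {detail}")


class NormalizationError(CTSynergyError):
    """No control wells available at the requested time point."""


class DegenerateControlError(CTSynergyError):
    """Control wells have non-positive mean corrected OD."""


class InsufficientDataError(CTSynergyError):
    """Fewer than two usable nonzero doses for a median-effect fit."""


class NonMonotoneResponseError(CTSynergyError):
    """The median-effect plot has a non-positive slope."""


class MissingSeriesError(CTSynergyError):
    """A required dose-response series is absent from the input records."""

    def __init__(self, series: str):
        self.series = series
        super().__init__(f"required series not found in records: {series!r}")


class SimulationConfigError(CTSynergyError):
    """A synthetic-data configuration is invalid or not solvable."""


class CellCycleConvergenceError(CTSynergyError):
    """EM failed to converge within the iteration cap; carries the last iterate."""

    def __init__(self, last_iterate, n_iter: int):
        self.last_iterate = last_iterate
        self.n_iter = n_iter
        super().__init__(f"cell-cycle EM did not converge within {n_iter} iterations")
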