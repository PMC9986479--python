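"""Exception hierarchy for sbmclust."""


class SbmClustError(Exception):
    """Base class for all sbmclust errors."""


class ParameterError(SbmClustError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFeatureError(SbmClustError, ValueError):
    """A feature column is constant, so min-max normalisation is undefined.

    The message names the offending column index.
    """

    def __init__(self, column: int):
        self.column = column
        super().__init__(
            f"feature column {column} is constant (max == min); "
            "min-max normalisation is undefined for it"
        )


class ContractError(SbmClustError, ValueError):
    """Internal pipeline contract violated (e.g. out-of-range coordinates)."""


class CellBudgetError(SbmClustError, MemoryError):
    """The dense chunk array PN**N would exceed the configured cell budget."""
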