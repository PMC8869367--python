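"""Exception types raised across the package.

Every exception carries a short machine-readable ``code`` so CLI wrappers and
tests can dispatch on the failure class without parsing messages.
"""

from __future__ import annotations


class RgstabError(ValueError):
    """Base class for all rgstab errors."""

    code: str = "ERROR"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class MatrixFormatError(RgstabError):
    """Malformed Ct matrix file (duplicates, non-numeric cells, empty)."""

    code = "BAD_MATRIX"


class SpikeMissingError(RgstabError):
    """Spike-in value absent for a sample that needs equalization."""

    code = "SPIKE_MISSING"

    def __init__(self, sample_id: str):
        super().__init__(f"spike-in Ct is missing for sample {sample_id!r}")
        self.sample_id = sample_id


class EmptyPanelError(RgstabError):
    """No candidate gene survived presence filtering."""

    code = "EMPTY_PANEL"


class DegenerateDataError(RgstabError):
    """Statistic undefined on the given data (e.g. zero variance)."""

    code = "DEGENERATE"
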