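"""Error types shared across the pipeline.

A failed well is a recorded outcome, not a crash: stages raise
:class:`NoCallError` with a machine-readable ``error_code`` and the batch
runner converts it into a no-call row. Genuine misuse (bad paths, invalid
parameters) raises ordinary exceptions.
"""

from __future__ import annotations

# Every error_code that can appear in the results table.
ERROR_CODES = frozenset(
    {
        "corrupted_video",
        "no_embryo",
        "no_motion",
        "no_periodic_region",
        "below_floor",
        "early_movement",
        "discordant",
    }
)


class FishbeatError(Exception):
    """Base class for package errors."""


class NoCallError(FishbeatError):
    """A well could not be called; carries the reason for the results row."""

    def __init__(self, error_code: str, message: str = ""):
        if error_code not in ERROR_CODES:
            raise ValueError(f"unknown error_code: {error_code!r}")
        self.error_code = error_code
        super().__init__(message or error_code)
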