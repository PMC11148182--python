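"""Typed errors carrying a short machine-readable code.

Every failure mode the pipeline can hit deliberately (bad input, degenerate
data, protocol violations) raises :class:`IcarError` with a stable ``code``
string so callers and the CLI can branch on it without parsing messages.
"""

from __future__ import annotations


class IcarError(ValueError):
    """Pipeline error with a stable short code (e.g. ``"missing_condition"``)."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return base if base == self.code else f"{self.code}: {base}"
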