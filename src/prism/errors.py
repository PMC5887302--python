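"""Package-wide error type with stable machine-readable codes."""

from __future__ import annotations


class PrismError(Exception):
    """Error raised by prism operations.

    Parameters
    ----------
    code:
        Stable, kebab-case error code (e.g. ``"empty-dataset"``) suitable
        for programmatic handling and CLI diagnostics.
    message:
        Human-readable detail.
    """

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)
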