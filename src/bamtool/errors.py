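"""Exception hierarchy shared across the package."""


class BamError(Exception):
    """Base class for all package-specific errors."""


class InputError(BamError):
    """Bad user input: missing files, malformed records, bad config values."""


class StructureParseError(InputError):
    """A structure notation string could not be parsed at all."""

    def __init__(self, text: str, detail: str = "") -> None:
        self.text = text
        msg = f"cannot parse structure notation: {text!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ValenceError(InputError):
    """A structure parsed but violates valence rules."""

    def __init__(self, text: str, detail: str = "") -> None:
        self.text = text
        msg = f"valence violation in structure: {text!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SpectrumFormatError(InputError):
    """A spectrum record is malformed; carries the record index."""

    def __init__(self, record_index: int, detail: str) -> None:
        self.record_index = record_index
        super().__init__(f"malformed spectrum record #{record_index}: {detail}")


class FingerprintMismatchError(BamError):
    """Fingerprints were computed with incompatible parameters."""


class PipelineError(BamError):
    """A pipeline stage failed; names the stage and record context."""

    def __init__(self, stage: str, detail: str) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")
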