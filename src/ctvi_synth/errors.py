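"""Exception types shared across the pipeline."""


class CtviError(Exception):
    """Base class for all package errors."""


class FormatError(CtviError):
    """An on-disk image could not be interpreted (bad header, oblique
    orientation, non-finite voxels)."""


class ParameterError(CtviError, ValueError):
    """An operation was called with invalid parameters or mismatched grids."""


class DegenerateCaseError(CtviError):
    """A case produced a degenerate intermediate (e.g. empty lung mask) and
    cannot proceed through the pipeline."""


class DataError(CtviError):
    """Training/evaluation data is structurally unusable (e.g. empty stack)."""
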