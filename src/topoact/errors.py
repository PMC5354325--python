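"""Exception types shared across the pipeline."""


class TopoactError(Exception):
    """Base class for all package errors."""


class ParameterError(TopoactError, ValueError):
    """A simulation or pipeline parameter is invalid or infeasible."""


class InputError(TopoactError, ValueError):
    """Malformed numerical input (non-finite values, shape mismatch, ...)."""


class ZeroVarianceError(InputError):
    """A node time course has zero variance; correlations are undefined."""


class DegenerateCorrelationError(InputError):
    """|r| = 1 off the diagonal: Fisher's z diverges."""


class RankDeficientDesignError(InputError):
    """Nuisance design matrix is rank deficient after adding the intercept."""


class ParticipantExcludedError(TopoactError):
    """Fewer than ``min_frames`` frames survive scrubbing.

    Mirrors the cohort rule that participants with too little usable
    resting-state data are discarded from further analyses. The caller
    decides how to handle exclusion at the cohort level.
    """

    def __init__(self, n_kept: int, min_frames: int):
        self.n_kept = n_kept
        self.min_frames = min_frames
        super().__init__(
            f"only {n_kept} frames survive scrubbing "
            f"(minimum required: {min_frames}); participant excluded"
        )


class UndefinedCorrelationError(TopoactError, ValueError):
    """A correlation-based score is undefined (constant input vector)."""


class EmptyCellError(TopoactError, ValueError):
    """A role-by-system-type cell contains no nodes."""
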