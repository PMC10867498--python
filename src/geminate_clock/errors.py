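"""Exception hierarchy for the geminate-clock pipeline."""


class GeminateClockError(Exception):
    """Base class for all package errors."""


class AlignmentError(GeminateClockError):
    """Malformed or inconsistent alignment input."""


class PartitionError(GeminateClockError):
    """Malformed sample-to-group table or missing assignments."""


class DistanceError(GeminateClockError):
    """Undefined pairwise distance (e.g. no shared valid sites)."""


class SaturationError(DistanceError):
    """Observed divergence too high for the distance correction.

    Raised when a logarithm argument of the TN93 correction is
    non-positive; carries the offending pair of sample IDs.
    """

    def __init__(self, id_a: str, id_b: str, detail: str = ""):
        self.pair = (id_a, id_b)
        msg = f"distance saturated for pair ({id_a}, {id_b})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class TreeError(GeminateClockError):
    """Invalid tree input (unparseable Newick, missing branch lengths)."""


class OptimizationError(GeminateClockError):
    """Numerical optimizer failed to converge."""


class ConfigError(GeminateClockError):
    """Invalid simulation or pipeline configuration."""
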