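"""Exception hierarchy for seqseg."""


class SeqSegError(Exception):
    """Base class for all seqseg errors."""


class InvalidSpecError(SeqSegError, ValueError):
    """A synthetic-signal specification violates its invariants."""


class EmptySignalError(SeqSegError, ValueError):
    """An operation that needs samples received an empty signal."""


class DegenerateSegmentError(SeqSegError, ValueError):
    """A candidate split produces a segment with zero sum of squares,
    or the candidate lies outside the kernel's convergence region."""


class DegenerateDataError(SeqSegError, ValueError):
    """Both segments carry zero energy; the variance-ratio posterior
    is improper and no test can be run."""


class NoCandidateError(SeqSegError, ValueError):
    """The candidate-changepoint grid is empty (segment too short for
    the requested edge margins); callers treat this as 'cannot split'."""
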