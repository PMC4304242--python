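"""Exception hierarchy shared across the package."""


class CausalPipeError(Exception):
    """Base class for all package errors."""


class SpanError(CausalPipeError):
    """A token or character span is out of range or malformed."""


class FormatError(CausalPipeError):
    """A serialised document (standoff, token layer, parse) is malformed."""


class TreeMembershipError(CausalPipeError):
    """A node was passed to a tree operation it does not belong to."""


class StageError(CausalPipeError):
    """A feature or operation was requested for the wrong pipeline stage."""


class StagingError(StageError):
    """A downstream flag (e.g. dependent-argument membership) was queried
    before the stage that produces it has run."""


class AlignmentError(CausalPipeError):
    """Two parallel structures (tags/tokens, gold/predicted sets) disagree
    in length or identity."""


class BlockedStateError(CausalPipeError):
    """A self-training loop reached a blocked state the policy could not
    resolve."""

    def __init__(self, loop: int, message: str | None = None):
        self.loop = loop
        super().__init__(message or f"blocked state in self-training loop {loop}: "
                                    "no instance above threshold and the "
                                    "blocked-state policy selected nothing")


class SamplingError(CausalPipeError):
    """A seed-set request cannot be satisfied by the available instances."""


class ConfigError(CausalPipeError):
    """An infeasible or inconsistent configuration."""


class WindowError(CausalPipeError):
    """An empty candidate sentence window for a cross-sentence argument."""


class NotFittedError(CausalPipeError):
    """A learner was used before being fitted."""
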