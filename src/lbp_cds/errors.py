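"""Exception hierarchy for the low back pain decision support engine.

All package-raised errors derive from :class:`LbpCdsError` so callers can
catch the whole family with a single clause; the subclasses distinguish the
contract that was violated (file format, knowledge-base integrity, adaptive
enablement, response domains, lookups, persistence versioning).
"""


class LbpCdsError(Exception):
    """Base class for all errors raised by this package."""


class KBFormatError(LbpCdsError):
    """A knowledge-base or session file could not be parsed."""


class KBIntegrityError(LbpCdsError):
    """A cross-reference inside a knowledge base does not resolve, or the
    knowledge base fails validation badly enough to refuse use."""


class EnablementError(LbpCdsError):
    """A finding was recorded for an item that the adaptive logic currently
    disables."""


class ResponseDomainError(LbpCdsError):
    """A response is outside the admissible response domain of its item, or a
    questionnaire rating is out of range."""


class NotFoundError(LbpCdsError):
    """A referenced entity (item, diagnosis, treatment, finding, scenario)
    does not exist in the current context."""


class VersionMismatchError(LbpCdsError):
    """A saved session was written against a different knowledge-base
    version than the one it is being loaded with."""


class EmptyPlanError(LbpCdsError):
    """A care plan was requested without any accepted working diagnosis."""
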