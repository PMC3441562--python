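"""Error taxonomy shared by the command engine and the HTTP frontend.

Names mirror the classical DAS status vocabulary; the wire mapping to
HTTP status codes lives in :mod:`dasserve.server`.
"""

from __future__ import annotations


class DasError(Exception):
    """Base of the DAS error taxonomy; ``status_name`` is the wire token."""

    status_name = "SERVER_ERROR"

    def __init__(self, message: str = ""):
        super().__init__(message or self.status_name)
        self.message = message or self.status_name


class BadCommand(DasError):
    """Unknown command token, or command on a source lacking the capability."""

    status_name = "BAD_COMMAND"


class BadDataSource(DasError):
    status_name = "BAD_DATA_SOURCE"


class BadCommandArgs(DasError):
    status_name = "BAD_COMMAND_ARGS"


class BadReferenceObject(DasError):
    """Unknown accession or out-of-bounds range on a reference source."""

    status_name = "BAD_REFERENCE_OBJECT"


class BadStylesheet(DasError):
    status_name = "BAD_STYLESHEET"


class ServerError(DasError):
    status_name = "SERVER_ERROR"


class ConfigError(ValueError):
    """Configuration file problem: syntax, missing field, duplicate id."""


class AdapterError(ValueError):
    """Adapter lookup or initialization failure."""


#: Distinguished signal returned by adapters when a queried segment id is
#: not covered by the source. The command layer decides the wire form:
#: annotation source -> in-document UNKNOWNSEGMENT block; reference
#: source -> BAD_REFERENCE_OBJECT error.
UNKNOWN_SEGMENT = object()
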