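"""HTTP frontend: bind DAS commands to HTTP, statuses, headers, gzip.

The servlet layer of the framework. :class:`DasApplication` owns the
validated configuration and the initialized adapters and turns
``(method, path, query, headers)`` into a :class:`Response`;
:func:`serve` exposes it over a threading HTTP server. Every response —
success or error — carries the ``X-DAS-Version``, ``X-DAS-Server`` and
``X-DAS-Capabilities`` headers, plus ``X-DAS-Status`` naming the error
taxonomy entry.
"""

from __future__ import annotations

import gzip
import logging
import threading
import time
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import urlsplit

from . import __version__
from .commands import execute, parse_request
from .config import ServerConfig, validate_config
from .errors import AdapterError, ConfigError, DasError
from .sources import AnnotationSource, adapter_registry, load_adapter
from .xml_io import serialize_document, xsl_decorate

log = logging.getLogger(__name__)

DAS_VERSION = "DAS/1.6"
SERVER_TOKEN = f"dasserve/{__version__}"

#: error taxonomy -> HTTP status (documented contract of this artifact)
STATUS_MAP = {
    "BAD_COMMAND": 400,
    "BAD_COMMAND_ARGS": 400,
    "BAD_DATA_SOURCE": 404,
    "BAD_REFERENCE_OBJECT": 404,
    "BAD_STYLESHEET": 404,
    "SERVER_ERROR": 500,
}


@dataclass
class Response:
    status: int
    headers: dict[str, str] = field(default_factory=dict)
    body: bytes = b""


def _accepts_gzip(request_headers: dict[str, str]) -> bool:
    accept = ""
    for k, v in request_headers.items():
        if k.lower() == "accept-encoding":
            accept = v
            break
    return "gzip" in accept.lower()


class DasApplication:
    """All configured sources behind one /das mount point.

    Adapter initialization happens eagerly in the constructor so a broken
    source (bad GFF path, missing property) fails fast at startup rather
    than at first request.
    """

    def __init__(self, cfg: ServerConfig):
        problems = validate_config(cfg, adapter_registry())
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))
        self.cfg = cfg
        self.adapters: dict[str, AnnotationSource] = {}
        for src in cfg.sources:
            try:
                self.adapters[src.source_id] = load_adapter(
                    src.adapter_name, src.properties
                )
            except AdapterError as exc:
                raise AdapterError(
                    f"source {src.source_id!r} failed to initialize: {exc}"
                ) from exc

    # -- request handling ----------------------------------------------------

    def _capabilities_header(self, source_id: str | None) -> str:
        if source_id is not None:
            src = self.cfg.source(source_id)
            if src is not None:
                return "; ".join(f"{c}/1.0" for c in src.capabilities)
        return "sources/1.0"

    def handle(
        self,
        method: str,
        path: str,
        query: str = "",
        request_headers: dict[str, str] | None = None,
    ) -> Response:
        """Turn one HTTP request into a Response; exceptions never escape."""
        request_headers = request_headers or {}
        if method not in ("GET", "HEAD"):
            resp = self._error_response(405, "BAD_COMMAND", None)
            resp.headers["Allow"] = "GET, HEAD"
            return resp
        source_id = None
        try:
            cmd = parse_request(path, query)
            source_id = cmd.source_id if cmd.command != "sources" else None
            doc = execute(cmd, self.cfg, self.adapters)
            payload = serialize_document(doc)
            if self.cfg.xslt_enabled and self.cfg.xslt_href:
                payload = xsl_decorate(payload, self.cfg.xslt_href)
            body = payload.bytes
            headers = {
                "Content-Type": payload.content_type,
                "X-DAS-Version": DAS_VERSION,
                "X-DAS-Server": SERVER_TOKEN,
                "X-DAS-Capabilities": self._capabilities_header(source_id),
                "X-DAS-Status": "OK",
            }
            if self.cfg.gzip_enabled and _accepts_gzip(request_headers):
                body = gzip.compress(body, mtime=0)  # mtime=0: deterministic bytes
                headers["Content-Encoding"] = "gzip"
            headers["Content-Length"] = str(len(body))
            if method == "HEAD":
                body = b""
            return Response(status=200, headers=headers, body=body)
        except DasError as exc:
            log.info("DAS error %s: %s", exc.status_name, exc.message)
            return self._error_response(
                STATUS_MAP[exc.status_name], exc.status_name, source_id
            )
        except Exception:
            # adapter/internal failure: detail goes to the log, never the wire
            log.exception("unhandled error serving %s?%s", path, query)
            return self._error_response(500, "SERVER_ERROR", source_id)

    def _error_response(
        self, status: int, das_status: str, source_id: str | None
    ) -> Response:
        body = (
            f'<?xml version="1.0" encoding="UTF-8"?>'
            f'<ERROR status="{das_status}"/>'
        ).encode()
        return Response(
            status=status,
            headers={
                "Content-Type": "text/xml",
                "Content-Length": str(len(body)),
                "X-DAS-Version": DAS_VERSION,
                "X-DAS-Server": SERVER_TOKEN,
                "X-DAS-Capabilities": self._capabilities_header(source_id),
                "X-DAS-Status": das_status,
            },
            body=body,
        )


class _Handler(BaseHTTPRequestHandler):
    app: DasApplication  # set on the subclass by serve()
    protocol_version = "HTTP/1.1"

    def _dispatch(self, method: str) -> None:
        split = urlsplit(self.path)
        started = time.monotonic()
        resp = self.app.handle(method, split.path, split.query, dict(self.headers))
        self.send_response(resp.status)
        for name, value in resp.headers.items():
            self.send_header(name, value)
        self.end_headers()
        if method != "HEAD":
            self.wfile.write(resp.body)
        log.info(
            "request path=%s status=%d bytes=%d duration_ms=%.1f",
            split.path, resp.status, len(resp.body),
            (time.monotonic() - started) * 1000,
        )

    def do_GET(self) -> None:  # noqa: N802 (http.server API)
        self._dispatch("GET")

    def do_HEAD(self) -> None:  # noqa: N802
        self._dispatch("HEAD")

    def do_POST(self) -> None:  # noqa: N802
        self._dispatch("POST")

    def log_message(self, format: str, *args) -> None:
        pass  # request logging handled above via the logging module


@dataclass
class ServiceHandle:
    """A running server; ``port`` is the bound port (useful with port=0)."""

    server: ThreadingHTTPServer
    thread: threading.Thread

    @property
    def port(self) -> int:
        return self.server.server_address[1]

    def shutdown(self) -> None:
        self.server.shutdown()
        self.server.server_close()
        self.thread.join(timeout=5)


def serve(cfg: ServerConfig, port: int = 8080, host: str = "127.0.0.1") -> ServiceHandle:
    """Start serving all configured sources; fails fast on adapter errors."""
    app = DasApplication(cfg)  # raises before binding if any source is broken
    handler = type("BoundHandler", (_Handler,), {"app": app})
    server = ThreadingHTTPServer((host, port), handler)
    server.daemon_threads = True
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return ServiceHandle(server=server, thread=thread)
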