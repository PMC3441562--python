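"""Server configuration: parsing, validation and serialization.

One declarative YAML file describes the whole server: general options
(compression, XSL decoration, entry-point page size) and an ordered list
of data sources, each binding display metadata and a coordinate system
to a named adapter plus an opaque properties map the adapter interprets.
The schema is documented in ``docs/config-format.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigError

CAPABILITIES = ("sources", "entry_points", "sequence", "types", "features", "stylesheet")

_SOURCE_ID_OK = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789._-"
)

DEFAULT_BASE_URL = "http://localhost:8080/das"
DEFAULT_PAGE_SIZE = 1000


@dataclass
class DataSourceConfig:
    """Declared metadata and adapter binding for one DAS source."""

    source_id: str
    title: str
    description: str = ""
    maintainer_email: str = ""
    version: str = "1.0"
    coordinate_authority: str = ""
    coordinate_source_type: str = ""
    organism_taxid: Optional[int] = None
    capabilities: tuple[str, ...] = ()
    adapter_name: str = ""
    properties: dict[str, str] = field(default_factory=dict)


@dataclass
class ServerConfig:
    base_url: str = DEFAULT_BASE_URL
    gzip_enabled: bool = False
    stylesheet_default_path: Optional[str] = None
    xslt_enabled: bool = False
    xslt_href: Optional[str] = None
    entry_points_page_size: int = DEFAULT_PAGE_SIZE
    sources: list[DataSourceConfig] = field(default_factory=list)

    def source(self, source_id: str) -> Optional[DataSourceConfig]:
        for s in self.sources:
            if s.source_id == source_id:
                return s
        return None


_REQUIRED_SOURCE_FIELDS = ("id", "title", "adapter")


def parse_server_config(text: str) -> ServerConfig:
    """Parse a YAML configuration document into a :class:`ServerConfig`.

    Unspecified optional fields take documented defaults (gzip off,
    page size 1000, no default stylesheet). Raises :class:`ConfigError`
    naming the line on syntax errors, the field and source on missing
    required fields, and the id on duplicate source ids.
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"configuration syntax error{line}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")

    server = raw.get("server") or {}
    if not isinstance(server, dict):
        raise ConfigError("'server' section must be a mapping")

    cfg = ServerConfig(
        base_url=str(server.get("base_url", DEFAULT_BASE_URL)),
        gzip_enabled=bool(server.get("gzip", False)),
        stylesheet_default_path=server.get("stylesheet"),
        xslt_enabled=bool(server.get("xslt", False)),
        xslt_href=server.get("xslt_href"),
        entry_points_page_size=int(server.get("entry_points_page_size", DEFAULT_PAGE_SIZE)),
    )
    if cfg.entry_points_page_size < 1:
        raise ConfigError("server.entry_points_page_size must be >= 1")

    seen: set[str] = set()
    for i, block in enumerate(raw.get("sources") or []):
        if not isinstance(block, dict):
            raise ConfigError(f"source #{i + 1}: each source must be a mapping")
        label = str(block.get("id", f"#{i + 1}"))
        for fname in _REQUIRED_SOURCE_FIELDS:
            if fname not in block:
                raise ConfigError(f"source {label}: missing required field '{fname}'")
        sid = str(block["id"])
        if sid in seen:
            raise ConfigError(f"duplicate source id '{sid}'")
        seen.add(sid)
        coords = block.get("coordinates") or {}
        caps = tuple(str(c) for c in (block.get("capabilities") or ()))
        props = {str(k): str(v) for k, v in (block.get("properties") or {}).items()}
        cfg.sources.append(
            DataSourceConfig(
                source_id=sid,
                title=str(block["title"]),
                description=str(block.get("description", "")),
                maintainer_email=str(block.get("maintainer", "")),
                version=str(block.get("version", "1.0")),
                coordinate_authority=str(coords.get("authority", "")),
                coordinate_source_type=str(coords.get("source_type", "")),
                organism_taxid=(
                    int(coords["taxid"]) if coords.get("taxid") is not None else None
                ),
                capabilities=caps,
                adapter_name=str(block["adapter"]),
                properties=props,
            )
        )
    return cfg


def serialize_config(cfg: ServerConfig) -> str:
    """Inverse of :func:`parse_server_config` (structural round-trip)."""
    server: dict = {
        "base_url": cfg.base_url,
        "gzip": cfg.gzip_enabled,
        "xslt": cfg.xslt_enabled,
        "entry_points_page_size": cfg.entry_points_page_size,
    }
    if cfg.stylesheet_default_path is not None:
        server["stylesheet"] = cfg.stylesheet_default_path
    if cfg.xslt_href is not None:
        server["xslt_href"] = cfg.xslt_href
    sources = []
    for s in cfg.sources:
        block: dict = {
            "id": s.source_id,
            "title": s.title,
            "adapter": s.adapter_name,
            "description": s.description,
            "maintainer": s.maintainer_email,
            "version": s.version,
        }
        coords: dict = {}
        if s.coordinate_authority:
            coords["authority"] = s.coordinate_authority
        if s.coordinate_source_type:
            coords["source_type"] = s.coordinate_source_type
        if s.organism_taxid is not None:
            coords["taxid"] = s.organism_taxid
        if coords:
            block["coordinates"] = coords
        if s.capabilities:
            block["capabilities"] = list(s.capabilities)
        if s.properties:
            block["properties"] = dict(s.properties)
        sources.append(block)
    return yaml.safe_dump(
        {"server": server, "sources": sources},
        sort_keys=False,
        allow_unicode=True,
        default_flow_style=False,
    )


def validate_config(
    cfg: ServerConfig, registry: dict[str, frozenset[str]]
) -> list[str]:
    """Check config invariants against an adapter-capability registry.

    Returns violation descriptions (empty list means valid); never raises.
    """
    violations: list[str] = []
    if cfg.entry_points_page_size < 1:
        violations.append("server.entry_points_page_size: must be >= 1")
    seen: set[str] = set()
    for s in cfg.sources:
        if not s.source_id or not set(s.source_id) <= _SOURCE_ID_OK:
            violations.append(
                f"source {s.source_id!r}: id must match [A-Za-z0-9._-]+"
            )
        if s.source_id in seen:
            violations.append(f"source {s.source_id!r}: duplicate id")
        seen.add(s.source_id)
        unknown_caps = set(s.capabilities) - set(CAPABILITIES)
        if unknown_caps:
            violations.append(
                f"source {s.source_id!r}: unknown capabilities {sorted(unknown_caps)}"
            )
        if s.adapter_name not in registry:
            violations.append(
                f"source {s.source_id!r}: unknown adapter {s.adapter_name!r}"
            )
        else:
            # every adapter implicitly supports the sources listing
            unsupported = set(s.capabilities) - {"sources"} - registry[s.adapter_name]
            if unsupported:
                violations.append(
                    f"source {s.source_id!r}: adapter {s.adapter_name!r} does not "
                    f"support {sorted(unsupported)}"
                )
    return violations
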