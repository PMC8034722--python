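"""Resource descriptors and resolvers.

A *resource* is a small, language-neutral description of how to reach either
a dataset or a computation service: a URL (where), an optional format (how it
is encoded, when the URL suffix is not enough), and optional credentials
split into an identity and a secret. Descriptors are resolved through a
registry of pluggable resolvers into *clients* that know how to materialise
tabular data or run a whitelisted local command. Resolution is lazy: no I/O
happens until data are actually requested, so a descriptor for a dataset the
caller has no permission to read can still be passed around safely.

Credentials deliberately live outside the URL: user-info in the authority is
rejected at parse time, so a secret can never leak through a logged URL.
"""

from __future__ import annotations

import sqlite3
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence
from urllib.parse import parse_qsl, urlencode, urlsplit, urlunsplit

import pandas as pd
import yaml


class ResourceError(Exception):
    """Base class for resource handling failures."""


class UrlParseError(ResourceError):
    pass


class UnresolvableResourceError(ResourceError):
    pass


class NotADataResourceError(ResourceError):
    pass


class CommandNotAllowedError(ResourceError):
    pass


class ResourceIOError(ResourceError):
    """Read failure. Carries the descriptor *name*, never the secret."""


_SECRET_MASK = "***"


@dataclass(frozen=True)
class ParsedUrl:
    """RFC 3986 decomposition of a resource URL.

    ``query`` holds percent-decoded key/value pairs. :meth:`unparse`
    reassembles a normalized URL such that parse -> unparse -> parse is the
    identity.
    """

    scheme: str
    authority: str | None
    path: str
    query: Mapping[str, str] = field(default_factory=dict)

    def unparse(self) -> str:
        qs = urlencode(dict(self.query))
        return urlunsplit((self.scheme, self.authority or "", self.path, qs, ""))


def parse_resource_url(url: str) -> ParsedUrl:
    """Decompose ``url`` into scheme / authority / path / query.

    Raises :class:`UrlParseError` when the scheme is missing or the authority
    embeds user-info (credentials belong in the descriptor's identity/secret
    fields, not in the URL).
    """
    if not isinstance(url, str) or not url.strip():
        raise UrlParseError("resource URL must be a non-empty string")
    parts = urlsplit(url)
    if not parts.scheme:
        raise UrlParseError(f"resource URL has no scheme: {url!r}")
    if parts.username is not None or parts.password is not None:
        raise UrlParseError(
            "user-info in the URL authority is not allowed; "
            "use the descriptor identity/secret fields"
        )
    query = dict(parse_qsl(parts.query, keep_blank_values=True))
    return ParsedUrl(parts.scheme, parts.netloc or None, parts.path, query)


#: Fixed file-suffix -> format table. An explicit format always overrides.
SUFFIX_FORMATS: tuple[tuple[str, str], ...] = (
    (".vcf.gz", "vcf"),
    (".vcf", "vcf"),
    (".csv", "csv"),
    (".tsv", "tsv"),
    (".txt", "tsv"),
)


def infer_format(parsed: ParsedUrl, explicit_format: str | None = None) -> str:
    """Return the data format of a resource.

    The descriptor's explicit format, when present, always wins; otherwise
    the file-name suffix of the URL path is consulted. Unknown suffixes give
    ``"unknown"`` rather than an error: some storage systems use opaque
    identifiers as paths and only the format property can disambiguate.
    """
    if explicit_format:
        return explicit_format
    path = parsed.path.lower()
    for suffix, fmt in SUFFIX_FORMATS:
        if path.endswith(suffix):
            return fmt
    return "unknown"


@dataclass(frozen=True)
class ResourceDescriptor:
    """How to reach a dataset or computation service.

    ``name`` is an optional, not necessarily unique, human label. ``secret``
    is masked in every rendering of the descriptor.
    """

    url: str
    format: str | None = None
    name: str | None = None
    identity: str | None = None
    secret: str | None = None

    def __post_init__(self) -> None:
        parse_resource_url(self.url)  # validates scheme + no user-info

    @property
    def parsed(self) -> ParsedUrl:
        return parse_resource_url(self.url)

    @property
    def resolved_format(self) -> str:
        return infer_format(self.parsed, self.format)

    @property
    def label(self) -> str:
        return self.name or self.url

    def __repr__(self) -> str:  # never reveal the secret
        secret = _SECRET_MASK if self.secret is not None else None
        return (
            f"ResourceDescriptor(url={self.url!r}, format={self.format!r}, "
            f"name={self.name!r}, identity={self.identity!r}, secret={secret!r})"
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "url": self.url,
            "format": self.format,
            "identity": self.identity,
            "secret": self.secret,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ResourceDescriptor":
        known = {"name", "url", "format", "identity", "secret"}
        unknown = set(data) - known
        if unknown:
            raise ResourceError(f"unknown descriptor keys: {sorted(unknown)}")
        if "url" not in data:
            raise ResourceError("descriptor requires a url")
        return cls(
            url=data["url"],
            format=data.get("format"),
            name=data.get("name"),
            identity=data.get("identity"),
            secret=data.get("secret"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ResourceDescriptor":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise ResourceError(f"descriptor file {path} is not a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Clients

KIND_TABULAR_FILE = "tabular-file"
KIND_SQL_TABLE = "sql-table"
KIND_GENOTYPE_FILE = "genotype-file"
KIND_COMPUTATION = "computation"


class ResourceClient:
    """Base connection client; also serves as the client *handle*.

    Construction performs no I/O (laziness contract): a client can be built
    for a nonexistent file and only fails when data are requested.
    """

    kind: str = "abstract"

    def __init__(self, descriptor: ResourceDescriptor):
        self.descriptor = descriptor

    def as_table(self) -> pd.DataFrame:
        raise NotADataResourceError(
            f"resource {self.descriptor.label!r} is not a data resource"
        )

    def execute(self, command: str, args: Sequence[str] = ()) -> str:
        raise NotADataResourceError(
            f"resource {self.descriptor.label!r} is not a computation resource"
        )

    def __repr__(self) -> str:
        return f"{type(self).__name__}(kind={self.kind!r}, descriptor={self.descriptor!r})"


def _local_path(parsed: ParsedUrl, descriptor: ResourceDescriptor) -> Path:
    if parsed.scheme in ("http", "https"):
        # Network fetch sits behind the same contract but is intentionally a
        # stub at desk scale; only local locations are materialised.
        raise ResourceIOError(
            f"network fetch is not enabled for resource {descriptor.label!r}; "
            "use a file:// location"
        )
    return Path(parsed.path)


class TabularFileClient(ResourceClient):
    kind = KIND_TABULAR_FILE

    _SEPARATORS = {"csv": ",", "tsv": "\t"}

    def as_table(self) -> pd.DataFrame:
        d = self.descriptor
        fmt = d.resolved_format
        path = _local_path(d.parsed, d)
        try:
            return pd.read_csv(path, sep=self._SEPARATORS[fmt])
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ResourceIOError(
                f"cannot read tabular resource {d.label!r}: {type(exc).__name__}"
            ) from exc


class SqlTableClient(ResourceClient):
    """Embedded file-backed SQL table.

    The URL path names the database file with its last segment naming the
    table, e.g. ``sqlite:///data/study.db/pheno``.
    """

    kind = KIND_SQL_TABLE

    def _split(self) -> tuple[Path, str]:
        p = Path(self.descriptor.parsed.path)
        return p.parent, p.name

    def as_table(self) -> pd.DataFrame:
        d = self.descriptor
        db_path, table = self._split()
        if not db_path.exists():
            raise ResourceIOError(f"database for resource {d.label!r} not found")
        try:
            with sqlite3.connect(db_path) as conn:
                exists = conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table' AND name=?",
                    (table,),
                ).fetchone()
                if exists is None:
                    raise ResourceIOError(
                        f"table {table!r} missing in resource {d.label!r}"
                    )
                return pd.read_sql_query(f'SELECT * FROM "{table}"', conn)
        except sqlite3.Error as exc:
            raise ResourceIOError(
                f"cannot read SQL resource {d.label!r}: {type(exc).__name__}"
            ) from exc


class VcfFileClient(ResourceClient):
    kind = KIND_GENOTYPE_FILE

    def as_genotype_study(self):
        from .gwas import read_vcf_genotypes

        d = self.descriptor
        path = _local_path(d.parsed, d)
        if not path.exists():
            raise ResourceIOError(f"VCF for resource {d.label!r} not found")
        return read_vcf_genotypes(path)

    def as_table(self) -> pd.DataFrame:
        # sample id + one alt-allele dosage column per variant
        return self.as_genotype_study().to_frame()


class ShellCommandClient(ResourceClient):
    """Whitelisted local shell computation.

    The descriptor's query declares the allowed commands, e.g.
    ``shell://localhost/usr/bin?exec=plink,echo``. Anything else is refused.
    """

    kind = KIND_COMPUTATION

    def __init__(self, descriptor: ResourceDescriptor):
        super().__init__(descriptor)
        self.last_exit_status: int | None = None

    @property
    def whitelist(self) -> tuple[str, ...]:
        raw = self.descriptor.parsed.query.get("exec", "")
        return tuple(c for c in raw.split(",") if c)

    def execute(self, command: str, args: Sequence[str] = ()) -> str:
        if command not in self.whitelist:
            raise CommandNotAllowedError(
                f"command {command!r} is not whitelisted for resource "
                f"{self.descriptor.label!r} (allowed: {list(self.whitelist)})"
            )
        proc = subprocess.run(
            [command, *args], capture_output=True, text=True, check=False
        )
        self.last_exit_status = proc.returncode
        if proc.returncode != 0:
            raise ResourceError(
                f"command {command!r} exited with status {proc.returncode}: "
                f"{proc.stderr.strip()}"
            )
        return proc.stdout


def client_as_table(handle: ResourceClient) -> pd.DataFrame:
    """Materialise a data client as a table (first row of the file = header)."""
    return handle.as_table()


def exec_computation(
    handle: ResourceClient, command: str, args: Sequence[str] = ()
) -> str:
    """Run a whitelisted command on a computation client, returning stdout."""
    return handle.execute(command, args)


# ---------------------------------------------------------------------------
# Resolvers

class Resolver(Protocol):
    name: str

    def matches(self, descriptor: ResourceDescriptor) -> bool: ...

    def make_client(self, descriptor: ResourceDescriptor) -> ResourceClient: ...


@dataclass(frozen=True)
class SimpleResolver:
    """Predicate + factory pair; the building block for registry extensions."""

    name: str
    predicate: Callable[[ResourceDescriptor], bool]
    factory: Callable[[ResourceDescriptor], ResourceClient]

    def matches(self, descriptor: ResourceDescriptor) -> bool:
        return self.predicate(descriptor)

    def make_client(self, descriptor: ResourceDescriptor) -> ResourceClient:
        return self.factory(descriptor)


class ResolverRegistry:
    """Ordered resolver collection; first registered match wins."""

    def __init__(self) -> None:
        self._resolvers: list[Resolver] = []

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self._resolvers)

    def register(self, resolver: Resolver) -> "ResolverRegistry":
        if resolver.name in self.names:
            raise ResourceError(f"resolver {resolver.name!r} already registered")
        self._resolvers.append(resolver)
        return self

    def resolve(self, descriptor: ResourceDescriptor) -> ResourceClient:
        for resolver in self._resolvers:
            if resolver.matches(descriptor):
                return resolver.make_client(descriptor)
        raise UnresolvableResourceError(
            f"no resolver for resource {descriptor.label!r} "
            f"(scheme={descriptor.parsed.scheme!r}, "
            f"format={descriptor.resolved_format!r})"
        )


def register_resolver(registry: ResolverRegistry, resolver: Resolver) -> ResolverRegistry:
    return registry.register(resolver)


def resolve_client(
    registry: ResolverRegistry, descriptor: ResourceDescriptor
) -> ResourceClient:
    return registry.resolve(descriptor)


def _is_file_like(d: ResourceDescriptor) -> bool:
    return d.parsed.scheme in ("file", "http", "https")


def default_registry() -> ResolverRegistry:
    """Registry with the built-in resolvers, consulted in this order:

    delimited files, embedded SQL tables, VCF genotype files, local shell
    computations.
    """
    reg = ResolverRegistry()
    reg.register(
        SimpleResolver(
            "tabular-file",
            lambda d: _is_file_like(d) and d.resolved_format in ("csv", "tsv"),
            TabularFileClient,
        )
    )
    reg.register(
        SimpleResolver(
            "sql-table",
            lambda d: d.parsed.scheme == "sqlite",
            SqlTableClient,
        )
    )
    reg.register(
        SimpleResolver(
            "genotype-file",
            lambda d: _is_file_like(d) and d.resolved_format == "vcf",
            VcfFileClient,
        )
    )
    reg.register(
        SimpleResolver(
            "shell-command",
            lambda d: d.parsed.scheme == "shell",
            ShellCommandClient,
        )
    )
    return reg


def file_url(path: str | Path) -> str:
    """Convenience: absolute filesystem path -> ``file://`` URL."""
    return "file://" + str(Path(path).absolute())
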