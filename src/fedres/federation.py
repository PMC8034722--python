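"""Client-server fabric for federated analysis.

One central analysis client talks to several study-server nodes. Each node
holds raw data in a private environment, resolves its own resource
descriptors (credentials never leave the node), and answers only whitelisted
operations whose results pass the node's disclosure filters. Every
request/response crosses a mandatory JSON serialization boundary even for
in-process nodes, so "only aggregates travel" is enforced structurally: a
payload that cannot be rendered as plain JSON aggregates cannot leave.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .disclosure import DisclosureBlocked, DisclosureConfig, check_cell_counts, guard_payload
from .resources import (
    KIND_COMPUTATION,
    KIND_GENOTYPE_FILE,
    ResolverRegistry,
    ResourceDescriptor,
    default_registry,
)


class FederationError(Exception):
    pass


@dataclass(frozen=True)
class GuardContext:
    """What the disclosure guard needs to judge an operation's payload:
    the node's record count and the declared aggregate dimension."""

    n_obs: int
    n_params: int | None = None


#: op name -> server-side implementation ``fn(node, **args) -> (payload, ctx)``
SERVER_OPS: dict[str, Callable] = {}

#: ops implemented but excluded from the default whitelist
UNSAFE_OPS: set[str] = set()


def server_op(name: str, unsafe: bool = False):
    """Register a server-side operation under ``name``."""

    def decorator(fn):
        if name in SERVER_OPS:
            raise FederationError(f"server op {name!r} already registered")
        SERVER_OPS[name] = fn
        if unsafe:
            UNSAFE_OPS.add(name)
        return fn

    return decorator


def default_allowed_ops() -> set[str]:
    return set(SERVER_OPS) - UNSAFE_OPS


@dataclass(frozen=True)
class AggregateResponse:
    """What a node sends back: an approved aggregate payload, or study-side
    messages explaining why there is none. Never both."""

    node_name: str
    ok: bool
    payload: object = None
    messages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ok:
            if self.payload is not None:
                raise FederationError("a failed response must not carry a payload")
            if not self.messages:
                raise FederationError("a failed response must carry messages")

    def to_dict(self) -> dict:
        return {
            "node": self.node_name,
            "ok": self.ok,
            "payload": self.payload,
            "messages": list(self.messages),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AggregateResponse":
        return cls(
            node_name=data["node"],
            ok=bool(data["ok"]),
            payload=data.get("payload"),
            messages=tuple(data.get("messages", ())),
        )


def _jsonable(value):
    """Coerce numpy containers/scalars to plain JSON types."""
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


class ServerNode:
    """One study's private environment.

    ``environment`` maps symbol names to materialised datasets (data frames,
    genotype studies, resolved computation clients). It is never serialized
    into any response; only operation payloads that pass the node's
    disclosure guard leave through :meth:`handle_request`.
    """

    def __init__(
        self,
        node_name: str,
        resources: Mapping[str, ResourceDescriptor] | None = None,
        disclosure: DisclosureConfig | None = None,
        allowed_ops: Sequence[str] | None = None,
        registry: ResolverRegistry | None = None,
    ) -> None:
        self.node_name = node_name
        self.resources: dict[str, ResourceDescriptor] = dict(resources or {})
        self.disclosure = disclosure if disclosure is not None else DisclosureConfig()
        self._allowed_ops = set(allowed_ops) if allowed_ops is not None else None
        self.registry = registry if registry is not None else default_registry()
        self.environment: dict[str, object] = {}
        self._cache: dict = {}

    @property
    def allowed_ops(self) -> set[str]:
        if self._allowed_ops is None:
            return default_allowed_ops()
        return self._allowed_ops

    def add_resource(self, name: str, descriptor: ResourceDescriptor) -> None:
        self.resources[name] = descriptor

    def get_dataset(self, symbol: str):
        if symbol not in self.environment:
            raise FederationError(f"no dataset bound to symbol {symbol!r}")
        return self.environment[symbol]

    # -- request handling ---------------------------------------------------

    def handle_request(self, request_json: str) -> str:
        """The node's entire public surface: JSON request in, JSON response
        out. All errors become ok=false responses; nothing raises across the
        boundary, so one failing node never halts a broadcast."""
        try:
            request = json.loads(request_json)
            op = request["op"]
            args = request.get("args", {})
        except (json.JSONDecodeError, KeyError, TypeError):
            response = self._fail(["malformed request"])
            return json.dumps(response.to_dict())
        response = self._dispatch(op, args)
        return json.dumps(response.to_dict())

    def _dispatch(self, op: str, args: Mapping) -> AggregateResponse:
        if op not in SERVER_OPS:
            return self._fail([f"unknown operation {op!r}"])
        if op not in self.allowed_ops:
            return self._fail([f"operation {op!r} is not allowed on this node"])
        try:
            payload, ctx = SERVER_OPS[op](self, **args)
        except DisclosureBlocked as exc:
            return self._fail(list(exc.messages))
        except Exception as exc:  # noqa: BLE001 - boundary: errors become messages
            return self._fail([self._scrub(f"{type(exc).__name__}: {exc}")])
        payload = _jsonable(payload)
        verdict = guard_payload(payload, ctx.n_obs, self.disclosure, ctx.n_params)
        if not verdict.allowed:
            return self._fail(list(verdict.messages))
        return AggregateResponse(self.node_name, True, payload)

    def _fail(self, messages: Sequence[str]) -> AggregateResponse:
        msgs = tuple(self._scrub(m) for m in messages) or ("operation failed",)
        return AggregateResponse(self.node_name, False, None, msgs)

    def _scrub(self, text: str) -> str:
        """Defence in depth: no resource secret ever appears in a message."""
        for descriptor in self.resources.values():
            if descriptor.secret:
                text = text.replace(descriptor.secret, "***")
        return text

    # -- configuration ------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping | str | Path, base_dir: Path | None = None) -> "ServerNode":
        """Build a node from a config document: ``node_name``, ``resources``
        (name -> descriptor mapping or descriptor-file path), ``disclosure``
        (mapping or file path), optional ``allowed_ops``."""
        if not isinstance(config, Mapping):
            path = Path(config)
            base_dir = base_dir or path.parent
            config = yaml.safe_load(path.read_text())
        base_dir = base_dir or Path.cwd()
        known = {"node_name", "resources", "disclosure", "allowed_ops"}
        unknown = set(config) - known
        if unknown:
            raise FederationError(f"unknown node config keys: {sorted(unknown)}")
        resources = {}
        for name, value in (config.get("resources") or {}).items():
            if isinstance(value, Mapping):
                resources[name] = ResourceDescriptor.from_dict(value)
            else:
                resources[name] = ResourceDescriptor.load(base_dir / value)
        disclosure = config.get("disclosure")
        if isinstance(disclosure, Mapping):
            disclosure = DisclosureConfig.from_dict(disclosure)
        elif disclosure is not None:
            disclosure = DisclosureConfig.load(base_dir / disclosure)
        return cls(
            node_name=config["node_name"],
            resources=resources,
            disclosure=disclosure,
            allowed_ops=config.get("allowed_ops"),
        )


class ClientSession:
    """Analyst-side connection to an ordered set of nodes.

    The session sees node names and aggregate payloads only; every exchange
    is appended to :attr:`log` to support serialization audits.
    """

    def __init__(self, nodes: Sequence[ServerNode]):
        self.nodes: tuple[ServerNode, ...] = tuple(nodes)
        self.log: list[dict] = []

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.node_name for n in self.nodes)

    def _send(self, node: ServerNode, request_json: str) -> AggregateResponse:
        response_json = node.handle_request(request_json)
        self.log.append(
            {"node": node.node_name, "request": request_json, "response": response_json}
        )
        return AggregateResponse.from_dict(json.loads(response_json))

    def broadcast(self, op_name: str, args: Mapping | None = None) -> list[AggregateResponse]:
        """Fan one request out to every node, in session order. A failing
        node yields ok=false without aborting the others."""
        if not self.nodes:
            raise FederationError("empty session: no nodes connected")
        request_json = json.dumps({"op": op_name, "args": _jsonable(args or {})})
        return [self._send(node, request_json) for node in self.nodes]

    def call(self, node_name: str, op_name: str, args: Mapping | None = None) -> AggregateResponse:
        for node in self.nodes:
            if node.node_name == node_name:
                request_json = json.dumps({"op": op_name, "args": _jsonable(args or {})})
                return self._send(node, request_json)
        raise FederationError(f"no node named {node_name!r} in the session")

    def assign_all(self, symbol: str, resource_name: str) -> list[AggregateResponse]:
        return self.broadcast("assign", {"symbol": symbol, "resource": resource_name})

    def log_lines(self) -> list[str]:
        lines = []
        for entry in self.log:
            resp = json.loads(entry["response"])
            req = json.loads(entry["request"])
            lines.append(
                f"{entry['node']}\t{req.get('op')}\tok={resp['ok']}\t"
                f"messages={len(resp.get('messages', []))}"
            )
        return lines


def session_broadcast(
    session: ClientSession, op_name: str, args: Mapping | None = None
) -> list[AggregateResponse]:
    return session.broadcast(op_name, args)


def node_aggregate(node: ServerNode, op_name: str, args: Mapping | None = None) -> AggregateResponse:
    """Run one whitelisted operation on one node, through the same JSON
    boundary a remote transport would use."""
    request_json = json.dumps({"op": op_name, "args": _jsonable(args or {})})
    return AggregateResponse.from_dict(json.loads(node.handle_request(request_json)))


def node_assign_resource(node: ServerNode, symbol: str, resource_name: str) -> AggregateResponse:
    return node_aggregate(node, "assign", {"symbol": symbol, "resource": resource_name})


# ---------------------------------------------------------------------------
# Core server operations

@server_op("assign")
def _op_assign(node: ServerNode, symbol: str, resource: str):
    """Resolve a registered resource descriptor and bind the materialised
    data to ``symbol``. The acknowledgement carries only the symbol name and
    the dataset dimensions."""
    if resource not in node.resources:
        raise FederationError(f"no such resource: {resource!r}")
    descriptor = node.resources[resource]
    client = node.registry.resolve(descriptor)
    if client.kind == KIND_COMPUTATION:
        node.environment[symbol] = client
        rows = cols = 0
    elif client.kind == KIND_GENOTYPE_FILE:
        study = client.as_genotype_study()
        node.environment[symbol] = study
        rows, cols = len(study.samples), len(study.variants)
    else:
        table = client.as_table()
        node.environment[symbol] = table
        rows, cols = table.shape
    node._cache.clear()
    payload = {"symbol": symbol, "kind": client.kind, "rows": int(rows), "cols": int(cols)}
    return payload, GuardContext(n_obs=int(rows))


@server_op("dims")
def _op_dims(node: ServerNode, symbol: str):
    data = node.get_dataset(symbol)
    if isinstance(data, pd.DataFrame):
        rows, cols = data.shape
    elif hasattr(data, "samples") and hasattr(data, "variants"):
        rows, cols = len(data.samples), len(data.variants)
    else:
        raise FederationError(f"symbol {symbol!r} has no tabular dimensions")
    return {"rows": int(rows), "cols": int(cols)}, GuardContext(n_obs=int(rows))


@server_op("colnames")
def _op_colnames(node: ServerNode, symbol: str):
    data = node.get_dataset(symbol)
    if not isinstance(data, pd.DataFrame):
        raise FederationError(f"symbol {symbol!r} is not a tabular dataset")
    names = [str(c) for c in data.columns]
    return names, GuardContext(n_obs=len(data), n_params=len(names))


@server_op("tabulate")
def _op_tabulate(node: ServerNode, symbol: str, column: str):
    """One-way contingency table, gated by the minimum-cell-count filter."""
    data = node.get_dataset(symbol)
    if not isinstance(data, pd.DataFrame):
        raise FederationError(f"symbol {symbol!r} is not a tabular dataset")
    if column not in data.columns:
        raise FederationError(f"no column {column!r} in symbol {symbol!r}")
    counts = data[column].value_counts(dropna=True).sort_index()
    check_cell_counts([int(c) for c in counts], node.disclosure).raise_if_blocked()
    payload = {"levels": [str(v) for v in counts.index], "counts": [int(c) for c in counts]}
    return payload, GuardContext(n_obs=len(data), n_params=len(counts))


@server_op("raw_column", unsafe=True)
def _op_raw_column(node: ServerNode, symbol: str, column: str):
    """Deliberately disclosive: returns an individual-level column. Excluded
    from the default whitelist; when whitelisted by a custodian it is still
    stopped by the raw-record guard unless checks are off."""
    data = node.get_dataset(symbol)
    values = data[column].tolist()
    return values, GuardContext(n_obs=len(data), n_params=None)
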