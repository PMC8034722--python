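"""Custodian-controlled disclosure filters.

Every aggregate computed on a study node must pass these filters before it
leaves the node. The custodian — never the analyst — chooses one of three
flavours:

* ``off``     — all checks disabled (non-sensitive data, maximum flexibility);
* ``minimal`` — only raw-record egress is blocked: nothing whose length
  equals the per-node record count may leave, but numeric filters on
  aggregates are not applied;
* ``full``    — all filters: raw-record egress, minimum non-empty
  contingency-cell counts, and a minimum observations-per-parameter ratio
  before any model fit.

The filters are deliberately monotone: everything blocked under ``minimal``
is blocked under ``full``, and everything allowed under ``full`` is allowed
under the laxer modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

MODES = ("off", "minimal", "full")


class DisclosureBlocked(Exception):
    """Raised server-side when a result violates the node's policy."""

    def __init__(self, messages: Sequence[str]):
        self.messages = tuple(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class DisclosureConfig:
    """Per-node disclosure policy.

    ``min_cell_count`` is the minimum count acceptable in a non-empty cell of
    a contingency table; ``glm_obs_per_param`` the minimum ratio of
    observations to model parameters before a fit may run;
    ``min_subset_size`` the smallest derived subset a server-side operation
    may create. Thresholds are set per node and are not reachable through any
    client-facing operation.
    """

    mode: str = "full"
    min_cell_count: int = 3
    glm_obs_per_param: float = 5.0
    min_subset_size: int = 3

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"disclosure mode must be one of {MODES}, got {self.mode!r}")
        if self.min_cell_count < 1 or self.min_subset_size < 1:
            raise ValueError("cell-count and subset thresholds must be positive")
        if self.glm_obs_per_param <= 0:
            raise ValueError("glm_obs_per_param must be positive")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "min_cell_count": self.min_cell_count,
            "glm_obs_per_param": self.glm_obs_per_param,
            "min_subset_size": self.min_subset_size,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DisclosureConfig":
        known = {"mode", "min_cell_count", "glm_obs_per_param", "min_subset_size"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown disclosure config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def load(cls, path: str | Path) -> "DisclosureConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass(frozen=True)
class DisclosureVerdict:
    """Outcome of a filter. A blocked verdict never carries a payload; the
    study-side messages are all the client gets."""

    allowed: bool
    messages: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.allowed and not self.messages:
            raise ValueError("a blocked verdict must carry at least one message")

    def raise_if_blocked(self) -> None:
        if not self.allowed:
            raise DisclosureBlocked(self.messages)


_ALLOW = DisclosureVerdict(True)


def check_cell_counts(
    counts: Sequence[int], config: DisclosureConfig
) -> DisclosureVerdict:
    """Minimum non-empty contingency-cell filter.

    Empty cells pass: the rule protects small *observed* groups, and a zero
    cell identifies nobody. Applied only under ``full`` checks; ``minimal``
    restricts raw-record egress, not aggregate tabulations.
    """
    if config.mode != "full":
        return _ALLOW
    bad = [c for c in counts if 0 < c < config.min_cell_count]
    if bad:
        return DisclosureVerdict(
            False,
            (
                f"cell-count filter: {len(bad)} non-empty cell(s) below the "
                f"minimum of {config.min_cell_count}",
            ),
        )
    return _ALLOW


def check_model_validity(
    n_obs: int, n_params: int, config: DisclosureConfig
) -> DisclosureVerdict:
    """Observations-per-parameter filter applied before any model fit."""
    if config.mode != "full":
        return _ALLOW
    required = config.glm_obs_per_param * n_params
    if n_obs < required:
        return DisclosureVerdict(
            False,
            (
                f"model-validity filter: {n_obs} observations for {n_params} "
                f"parameters; at least {config.glm_obs_per_param} observations "
                "per parameter are required",
            ),
        )
    return _ALLOW


def _component_lengths(payload) -> list[int]:
    """Lengths of every sequence component, at any nesting depth."""
    lengths: list[int] = []
    if isinstance(payload, (list, tuple)):
        lengths.append(len(payload))
        for item in payload:
            lengths.extend(_component_lengths(item))
    elif isinstance(payload, Mapping):
        for value in payload.values():
            lengths.extend(_component_lengths(value))
    return lengths


def _is_scalar(x) -> bool:
    return x is None or isinstance(x, (bool, int, float, str))


def _shape_of(payload):
    """Classify a payload: 'scalar', ('vector', n), ('matrix', r, c) or None."""
    if _is_scalar(payload):
        return "scalar"
    if isinstance(payload, (list, tuple)):
        if all(_is_scalar(v) for v in payload):
            return ("vector", len(payload))
        if payload and all(
            isinstance(r, (list, tuple)) and all(_is_scalar(v) for v in r)
            for r in payload
        ):
            widths = {len(r) for r in payload}
            if len(widths) == 1:
                return ("matrix", len(payload), widths.pop())
    return None


def guard_payload(
    payload,
    n_obs: int,
    config: DisclosureConfig,
    n_params: int | None = None,
) -> DisclosureVerdict:
    """Final gate on a candidate return value.

    Under ``minimal`` and ``full``, any component whose length equals the
    node's record count ``n_obs`` is treated as raw-record egress and
    blocked — this is the operationalisation of "analysts never see, copy or
    abstract the individual-level data". Under ``full``, the payload must
    additionally match an approved aggregate shape: a scalar, a vector of
    length at most ``n_params``, a matrix at most ``n_params`` square, a
    tabulation passing the cell-count filter, or a mapping of such
    components. Mappings may declare a tabulation via a ``counts`` key.
    """
    if config.mode == "off":
        return _ALLOW

    messages: list[str] = []
    if any(n == n_obs for n in _component_lengths(payload)):
        messages.append(
            "raw-record filter: payload contains a component whose length "
            "equals the per-node record count"
        )

    if config.mode == "full" and not messages:
        messages.extend(_shape_messages(payload, n_params, config))

    if messages:
        return DisclosureVerdict(False, tuple(messages))
    return _ALLOW


def _shape_messages(payload, n_params, config) -> list[str]:
    components = payload.values() if isinstance(payload, Mapping) else [payload]
    out: list[str] = []
    if isinstance(payload, Mapping) and "counts" in payload:
        counts = payload["counts"]
        if isinstance(counts, (list, tuple)):
            verdict = check_cell_counts([int(c) for c in counts], config)
            out.extend(verdict.messages)
    for comp in components:
        shape = _shape_of(comp)
        if shape is None:
            out.append("shape filter: payload component is not an approved aggregate shape")
        elif n_params is not None:
            if shape != "scalar":
                if shape[0] == "vector" and shape[1] > n_params:
                    out.append(
                        f"shape filter: vector of length {shape[1]} exceeds the "
                        f"declared parameter count {n_params}"
                    )
                elif shape[0] == "matrix" and max(shape[1], shape[2]) > n_params:
                    out.append(
                        f"shape filter: matrix {shape[1]}x{shape[2]} exceeds the "
                        f"declared parameter count {n_params}"
                    )
    return out
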