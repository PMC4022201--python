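"""Deterministic local emulation of a map/shuffle/reduce job.

One job = map every input payload, group keyed emissions by exact key
equality, call the reducer once per key in sorted key order, and collect a
separate passthrough channel for payloads the mapper emits directly
(bypassing the shuffle). Determinism stands in for the parallelism of a real
cluster: the output never depends on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Generic, Iterable, Sequence, TypeVar

P = TypeVar("P")  # payload
R = TypeVar("R")  # reduced output

#: Separator for structured join keys: <chain_id> SEP <pid> SEP <resource>.
#: A control character, so resource labels containing "_" cannot collide.
KEY_SEPARATOR = "\x01"


@dataclass(frozen=True)
class Keyed(Generic[P]):
    """A (join key, payload) emission routed through the shuffle."""

    key: str
    value: P

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("join key must be non-empty")


@dataclass(frozen=True)
class Direct(Generic[P]):
    """A payload emitted straight to the output, bypassing the reducer."""

    value: P


Emission = Keyed[P] | Direct[P]


@dataclass
class JobResult(Generic[P, R]):
    """Outputs of one job: reduced records plus the passthrough channel."""

    reduced: list[R] = field(default_factory=list)
    passthrough: list[P] = field(default_factory=list)


class JobError(RuntimeError):
    """A map or reduce function raised; carries the offending key/payload."""

    def __init__(self, stage: str, context: object, cause: BaseException) -> None:
        self.stage = stage
        self.context = context
        super().__init__(f"{stage} failed on {context!r}: {cause}")


def make_key(chain_id: str, pid: int, resource: str) -> str:
    """Encode a structured join key."""
    return f"{chain_id}{KEY_SEPARATOR}{pid}{KEY_SEPARATOR}{resource}"


def split_key(key: str) -> tuple[str, int, str]:
    """Decode a key produced by :func:`make_key`."""
    chain_id, pid, resource = key.split(KEY_SEPARATOR, 2)
    return chain_id, int(pid), resource


def run_job(
    inputs: Iterable[P],
    map_fn: Callable[[P], Sequence[Emission]],
    reduce_fn: Callable[[str, list], Sequence[R]],
) -> JobResult:
    """Execute one deterministic map → shuffle → reduce round.

    Every keyed emission is grouped with all emissions sharing its exact key;
    ``reduce_fn`` runs once per key, keys visited in sorted order. Direct
    emissions appear untouched in ``passthrough``. Both functions must be
    pure; an exception from either is wrapped in :class:`JobError` together
    with the payload or key being processed.
    """
    groups: dict[str, list] = {}
    result: JobResult = JobResult()
    for payload in inputs:
        try:
            emissions = map_fn(payload)
        except Exception as exc:
            raise JobError("map", payload, exc) from exc
        for emission in emissions:
            if isinstance(emission, Keyed):
                groups.setdefault(emission.key, []).append(emission.value)
            elif isinstance(emission, Direct):
                result.passthrough.append(emission.value)
            else:
                raise JobError(
                    "map", payload, TypeError(f"bad emission {emission!r}")
                )
    for key in sorted(groups):
        try:
            result.reduced.extend(reduce_fn(key, groups[key]))
        except Exception as exc:
            raise JobError("reduce", key, exc) from exc
    return result
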