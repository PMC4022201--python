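"""Formal model of property-chain reasoning.

A reasoning rule chain (RRC) is an ordered list of class-to-class rules, e.g.
Herb --treatment--> Disease --possibleDrug--> Drug --...--> Gene. Dropping
the classes leaves an ordered list of properties; composing consecutive
properties with the ⊗ operator yields OWL property chains (OPCs). The ordered
list of OPCs still awaiting composition is the property chain set (PCS); a
triple's PID is the position of its predicate in the current PCS, or -1 when
the predicate does not occur, in which case the triple is invisible to the
reasoner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import yaml

from .rdf_model import Triple

#: Separator used in canonical OPC names. Primitive property names may not
#: contain it, which makes the serialization reversible and collision-free.
OPC_SEPARATOR = "|"

#: PID of a triple whose predicate lies outside the current PCS.
PID_NONE = -1


@dataclass(frozen=True)
class RuleTriple:
    """One class-level reasoning rule: (source class, property, target class)."""

    source_class: str
    property: str
    target_class: str

    def __post_init__(self) -> None:
        for name, value in (
            ("source_class", self.source_class),
            ("property", self.property),
            ("target_class", self.target_class),
        ):
            if not value:
                raise ValueError(f"RuleTriple.{name} must be non-empty")
        if OPC_SEPARATOR in self.property:
            raise ValueError(
                f"property name may not contain {OPC_SEPARATOR!r}: {self.property!r}"
            )


@dataclass(frozen=True)
class ReasoningRuleChain:
    """An ordered chain of rules whose classes link end to end."""

    rules: tuple[RuleTriple, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("a reasoning rule chain needs at least one rule")
        for left, right in zip(self.rules, self.rules[1:]):
            if left.target_class != right.source_class:
                raise ValueError(
                    f"rule classes do not link: ...{left.target_class}) followed "
                    f"by ({right.source_class}..."
                )

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def source_class(self) -> str:
        return self.rules[0].source_class

    @property
    def sink_class(self) -> str:
        return self.rules[-1].target_class

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(r.property for r in self.rules)

    @classmethod
    def from_properties(
        cls, properties: Sequence[str], classes: Sequence[str] | None = None
    ) -> "ReasoningRuleChain":
        """Build a chain from a property list, synthesizing class names.

        ``classes`` must have one more entry than ``properties`` when given;
        otherwise placeholder class names ``C0..Cn`` are used.
        """
        if classes is None:
            classes = [f"C{i}" for i in range(len(properties) + 1)]
        if len(classes) != len(properties) + 1:
            raise ValueError(
                f"need {len(properties) + 1} classes for {len(properties)} "
                f"properties, got {len(classes)}"
            )
        return cls(
            tuple(
                RuleTriple(classes[i], p, classes[i + 1])
                for i, p in enumerate(properties)
            )
        )


@dataclass(frozen=True)
class OPC:
    """An OWL property chain: one or more primitive properties composed in order."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("an OPC needs at least one component")
        for c in self.components:
            if not c:
                raise ValueError("OPC components must be non-empty")
            if OPC_SEPARATOR in c:
                raise ValueError(
                    f"primitive property may not contain {OPC_SEPARATOR!r}: {c!r}"
                )

    @property
    def canonical_name(self) -> str:
        return OPC_SEPARATOR.join(self.components)

    @classmethod
    def from_name(cls, name: str) -> "OPC":
        return cls(tuple(name.split(OPC_SEPARATOR)))

    @classmethod
    def of(cls, *components: str) -> "OPC":
        return cls(components)

    def __len__(self) -> int:
        return len(self.components)

    def __str__(self) -> str:
        return self.canonical_name


def compose_opc(left: OPC, right: OPC) -> OPC:
    """The ⊗ operator: concatenate component lists (associative)."""
    return OPC(left.components + right.components)


@dataclass(frozen=True)
class PCS:
    """The ordered list of OPCs still to be composed; positions are PIDs."""

    opcs: tuple[OPC, ...]

    def __post_init__(self) -> None:
        if not self.opcs:
            raise ValueError("a PCS needs at least one OPC")

    def __len__(self) -> int:
        return len(self.opcs)

    def __getitem__(self, k: int) -> OPC:
        return self.opcs[k]

    def __iter__(self) -> Iterator[OPC]:
        return iter(self.opcs)

    @classmethod
    def of(cls, *names: str) -> "PCS":
        """Build from canonical OPC names (``|`` separates composed parts)."""
        return cls(tuple(OPC.from_name(n) for n in names))

    @property
    def final_opc(self) -> OPC:
        """The fully composed chain once reasoning has reached a fixpoint."""
        if len(self.opcs) != 1:
            raise ValueError("PCS not yet reduced to a single OPC")
        return self.opcs[0]

    def positions_of(self, predicate: str) -> tuple[int, ...]:
        """All PIDs at which ``predicate`` occurs (usually zero or one)."""
        return tuple(
            k for k, opc in enumerate(self.opcs) if opc.canonical_name == predicate
        )


def rrc_to_pcs(rrc: ReasoningRuleChain) -> PCS:
    """Initial PCS: one single-property OPC per rule, in rule order."""
    return PCS(tuple(OPC((p,)) for p in rrc.properties))


def assign_pid(triple: Triple, pcs: PCS) -> int | tuple[int, ...]:
    """PID of a triple under the current PCS.

    Returns the unique position whose OPC name equals the predicate, ``-1``
    when the predicate is absent, and the tuple of all positions in the
    degenerate case of a repeated property.
    """
    positions = pcs.positions_of(triple.predicate)
    if not positions:
        return PID_NONE
    if len(positions) == 1:
        return positions[0]
    return positions


def merge_first_two(pcs: PCS) -> PCS:
    """Compose the first two OPCs; the step the naive algorithm takes per iteration."""
    if len(pcs) < 2:
        raise ValueError("PCS already reduced; nothing to merge")
    merged = compose_opc(pcs[0], pcs[1])
    return PCS((merged,) + pcs.opcs[2:])


def halve_pcs(pcs: PCS) -> PCS:
    """Compose adjacent OPC pairs (0,1), (2,3), ...; odd tail carried over.

    New length is ceil(old/2) — the step the parity-rule algorithm takes per
    iteration, reaching a single OPC in ceil(log2 N) steps.
    """
    if len(pcs) < 2:
        raise ValueError("PCS already reduced; nothing to halve")
    out: list[OPC] = []
    for k in range(0, len(pcs) - 1, 2):
        out.append(compose_opc(pcs[k], pcs[k + 1]))
    if len(pcs) % 2:
        out.append(pcs[len(pcs) - 1])
    return PCS(tuple(out))


@dataclass(frozen=True)
class Chain:
    """One named chain of an OWL reasoning network, with its class endpoints."""

    chain_id: str
    pcs: PCS
    source_class: str = ""
    sink_class: str = ""


@dataclass(frozen=True)
class ORN:
    """OWL reasoning network: the chains executed together in one shared job."""

    chains: tuple[Chain, ...]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


@dataclass(frozen=True)
class ARS:
    """Associated result set: the (source class, sink class) pair per chain."""

    pairs: tuple[tuple[str, str], ...] = field(default=())

    @classmethod
    def from_orn(cls, orn: ORN) -> "ARS":
        return cls(tuple((c.source_class, c.sink_class) for c in orn.chains))


def load_chain_config(path: str | Path) -> tuple[ORN, ARS, dict[str, ReasoningRuleChain]]:
    """Parse a YAML chain configuration.

    Expected layout::

        chains:
          - id: herb_gene
            source_class: Herb
            sink_class: Gene
            properties: [treatment, possibleDrug, ...]
            classes: [Herb, Disease, ...]   # optional, len(properties)+1

    Returns the reasoning network, its associated result set, and the
    per-chain rule chains (placeholder classes where none were given).
    """
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "chains" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'chains' list")
    chains: list[Chain] = []
    rrcs: dict[str, ReasoningRuleChain] = {}
    for entry in raw["chains"]:
        try:
            chain_id = str(entry["id"])
            properties = [str(p) for p in entry["properties"]]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: each chain needs 'id' and 'properties'") from exc
        if not properties:
            raise ValueError(f"{path}: chain {chain_id!r} has no properties")
        classes = entry.get("classes")
        source = str(entry.get("source_class", ""))
        sink = str(entry.get("sink_class", ""))
        if classes is None and source and sink:
            classes = [source] + [f"C{i}" for i in range(1, len(properties))] + [sink]
        rrc = ReasoningRuleChain.from_properties(properties, classes)
        rrcs[chain_id] = rrc
        chains.append(
            Chain(
                chain_id=chain_id,
                pcs=rrc_to_pcs(rrc),
                source_class=source or rrc.source_class,
                sink_class=sink or rrc.sink_class,
            )
        )
    orn = ORN(tuple(chains))
    return orn, ARS.from_orn(orn), rrcs
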