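"""Naive iterative reasoner: one head-of-chain join per iteration.

Each iteration joins only the triples at chain positions 0 and 1 (on a
shared intermediate: object of the position-0 triple equals subject of the
position-1 triple), merges the first two OPCs of the PCS, and carries every
later-position triple forward untouched. A chain of N properties therefore
needs exactly N - 1 iterations, whatever the graph contains. Kept as the
baseline and correctness cross-check for the log-halving variant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chain_model import PCS, OPC, PID_NONE, assign_pid, compose_opc, merge_first_two
from .mr_engine import Direct, Emission, Keyed, make_key, run_job
from .rdf_model import Resource, Triple, TripleGraph

#: Tag for triples keyed on their object (position 0, left side of the join).
LEFT = "L"
#: Tag for triples keyed on their subject (position 1, right side).
RIGHT = "R"

TaggedTriple = tuple[str, Triple]


@dataclass(frozen=True)
class ReasoningResult:
    """Final associations plus the number of join jobs that produced them."""

    associations: frozenset[tuple[Resource, OPC, Resource]]
    iterations: int

    @property
    def pairs(self) -> frozenset[tuple[Resource, Resource]]:
        """Endpoint pairs only, for comparison against the brute-force oracle."""
        return frozenset((s, o) for s, _, o in self.associations)


def naive_map(triple: Triple, pcs: PCS, chain_id: str = "") -> list[Emission]:
    """Route one triple: join now (PID 0/1), keep for later (PID >= 2), or drop.

    Position-0 triples are keyed on their object and position-1 triples on
    their subject, so each reduce group holds exactly the candidates sharing
    one intermediate resource. A predicate occurring at several positions
    fans out to every role.
    """
    pid = assign_pid(triple, pcs)
    positions = (pid,) if isinstance(pid, int) else pid
    emissions: list[Emission] = []
    passthrough_done = False
    for k in positions:
        if k == PID_NONE:
            continue
        if k == 0:
            if not triple.object.is_literal:
                emissions.append(
                    Keyed(make_key(chain_id, 0, triple.object.identifier), (LEFT, triple))
                )
        elif k == 1:
            emissions.append(
                Keyed(make_key(chain_id, 0, triple.subject.identifier), (RIGHT, triple))
            )
        elif not passthrough_done:
            emissions.append(Direct(triple))
            passthrough_done = True
    return emissions


def naive_reduce(key: str, group: list[TaggedTriple], pcs: PCS) -> list[Triple]:
    """Join one intermediate resource's group: lefts x rights under OPC0 ⊗ OPC1."""
    merged = compose_opc(pcs[0], pcs[1])
    subjects = sorted({t.subject for tag, t in group if tag == LEFT})
    objects = sorted({t.object for tag, t in group if tag == RIGHT})
    return [
        Triple(s, merged.canonical_name, o) for s in subjects for o in objects
    ]


def naive_reason(graph: TripleGraph, pcs: PCS, trace=None) -> ReasoningResult:
    """Iterate head-of-chain joins until the PCS holds a single OPC.

    After each job the working graph becomes (derived ∪ passthrough) and the
    PCS loses its first element to composition. Unmatched position-0/1
    triples die with their group — the next PCS would assign them PID -1
    anyway. Associations are the triples bearing the fully composed chain's
    canonical name.
    """
    iterations = 0
    while len(pcs) > 1:
        current = pcs
        result = run_job(
            graph,
            lambda t: naive_map(t, current),
            lambda key, group: naive_reduce(key, group, current),
        )
        graph = TripleGraph(result.reduced) | TripleGraph(result.passthrough)
        pcs = merge_first_two(pcs)
        iterations += 1
        if trace is not None:
            trace(iterations, len(result.reduced), len(result.passthrough))
    final = pcs.final_opc
    associations = frozenset(
        (t.subject, final, t.object)
        for t in graph.triples
        if t.predicate == final.canonical_name
    )
    return ReasoningResult(associations=associations, iterations=iterations)
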