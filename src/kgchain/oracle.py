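"""Brute-force reference reasoner.

Walks the chain property by property with nested-loop joins, keeping only
endpoint pairs. Quadratic per hop and entirely independent of the
map/shuffle/reduce machinery, which is exactly what makes it a trustworthy
cross-check for the three production algorithms.
"""

from __future__ import annotations

from collections import defaultdict

from .chain_model import PCS
from .rdf_model import Resource, TripleGraph

Association = tuple[Resource, Resource]


def brute_force_associations(graph: TripleGraph, pcs: PCS) -> set[Association]:
    """All (source, sink) pairs connected by the full property sequence.

    The frontier starts at triples bearing the first primitive property and
    is repeatedly extended by matching each partial path's endpoint against
    subjects of the next property. Literals never extend a path (they have
    no outgoing edges by construction). Endpoint pairs are deduplicated.
    """
    properties: list[str] = []
    for opc in pcs:
        properties.extend(opc.components)

    by_predicate: dict[str, dict[Resource, set[Resource]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for t in graph.triples:
        by_predicate[t.predicate][t.subject].add(t.object)

    first = by_predicate.get(properties[0], {})
    # frontier: endpoint -> set of path sources reaching it
    frontier: dict[Resource, set[Resource]] = defaultdict(set)
    for subject, objects in first.items():
        for obj in objects:
            frontier[obj].add(subject)

    for prop in properties[1:]:
        step = by_predicate.get(prop, {})
        new_frontier: dict[Resource, set[Resource]] = defaultdict(set)
        for endpoint, sources in frontier.items():
            for obj in step.get(endpoint, ()):
                new_frontier[obj].update(sources)
        frontier = new_frontier
        if not frontier:
            break

    return {
        (source, endpoint)
        for endpoint, sources in frontier.items()
        for source in sources
    }
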