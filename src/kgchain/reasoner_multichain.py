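"""Multichain reasoner: several property chains share one iterated job.

Running chains one at a time re-reads the whole graph once per chain. Here
every iteration is a single shared job: the mapper prefixes each join key
with the chain's identifier, so a triple whose predicate lies on the
intersection of m chains fans out to m keyed emissions, each landing in a
reduce group private to its chain. Per chain the behaviour is exactly the
parity-rule algorithm; the shared-job structure changes scheduling, never
results. Iterations run until the longest chain completes —
ceil(log2 max_N) of them. A chain that finishes earlier parks its result
triples in a per-chain sink and contributes nothing afterwards.
"""

from __future__ import annotations

from .chain_model import ORN, ARS, PCS, PID_NONE, assign_pid, halve_pcs
from .mr_engine import Direct, Emission, Keyed, run_job, split_key
from .rdf_model import Triple, TripleGraph
from .reasoner_efficient import efficient_reduce, parity_join_key
from .reasoner_naive import ReasoningResult


def multichain_map(
    triple: Triple, chain_states: dict[str, PCS]
) -> list[Emission]:
    """Fan one triple out to every still-active chain that references it.

    ``chain_states`` maps chain id → that chain's current PCS (only chains
    with length >= 2 participate; completed chains are handled by the
    driver). Keys carry the chain id, isolating each chain's reduce groups.
    """
    emissions: list[Emission] = []
    passthrough_done = False
    for chain_id in sorted(chain_states):
        pcs = chain_states[chain_id]
        pid = assign_pid(triple, pcs)
        positions = (pid,) if isinstance(pid, int) else pid
        for k in positions:
            if k == PID_NONE:
                continue
            key = parity_join_key(k, triple, len(pcs), chain_id)
            if key is None:
                if not passthrough_done:
                    emissions.append(Direct(triple))
                    passthrough_done = True
            elif k % 2 == 0 and triple.object.is_literal:
                continue
            else:
                emissions.append(Keyed(key, (k, triple)))
    return emissions


def _multichain_reduce(
    key: str, group: list, chain_states: dict[str, PCS]
) -> list[Triple]:
    chain_id, _, _ = split_key(key)
    return efficient_reduce(key, group, chain_states[chain_id])


def multichain_reason(
    graph: TripleGraph, orn: ORN, ars: ARS | None = None, trace=None
) -> dict[str, ReasoningResult]:
    """Run every chain of the reasoning network over shared iterated jobs.

    Returns one :class:`ReasoningResult` per chain id. Each chain's
    association set equals what the single-chain parity-rule reasoner would
    produce on the original graph alone; the iteration count recorded per
    chain is the shared total, ceil(log2 of the longest chain's length).
    """
    if ars is not None and len(ars.pairs) != len(orn.chains):
        raise ValueError("ARS must align index-for-index with ORN chains")

    pcss: dict[str, PCS] = {c.chain_id: c.pcs for c in orn.chains}
    sinks: dict[str, set[Triple]] = {c.chain_id: set() for c in orn.chains}
    done: set[str] = set()
    iterations = 0

    def harvest(current_graph: TripleGraph) -> None:
        """Move completed chains' result triples into their sinks."""
        for chain_id, pcs in pcss.items():
            if chain_id in done or len(pcs) > 1:
                continue
            name = pcs.final_opc.canonical_name
            sinks[chain_id].update(
                t for t in current_graph.triples if t.predicate == name
            )
            done.add(chain_id)

    harvest(graph)  # chains of length 1 complete before any job
    while any(len(p) > 1 for p in pcss.values()):
        active = {cid: p for cid, p in pcss.items() if len(p) > 1}
        result = run_job(
            graph,
            lambda t: multichain_map(t, active),
            lambda key, group: _multichain_reduce(key, group, active),
        )
        graph = TripleGraph(result.reduced) | TripleGraph(result.passthrough)
        for chain_id in active:
            pcss[chain_id] = halve_pcs(pcss[chain_id])
        iterations += 1
        if trace is not None:
            trace(iterations, len(result.reduced), len(result.passthrough))
        harvest(graph)

    return {
        c.chain_id: ReasoningResult(
            associations=frozenset(
                (t.subject, pcss[c.chain_id].final_opc, t.object)
                for t in sinks[c.chain_id]
            ),
            iterations=iterations,
        )
        for c in orn.chains
    }
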