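"""Seeded generator of layered knowledge graphs with known ground truth.

Emulates the layered structure of a linked biomedical network — herbs treat
diseases, diseases have candidate drugs, drugs have targets, targets map to
proteins, proteins to Entrez records, records to gene symbols — plus
distractor assertions whose predicates belong to no reasoning chain.
Ground truth (which source-layer entity reaches which sink-layer entity
along the chain) is computed layer by layer during generation, independently
of every reasoner, so generated datasets double as test oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chain_model import ReasoningRuleChain, rrc_to_pcs
from .oracle import brute_force_associations
from .rdf_model import Resource, Triple, TripleGraph, write_ntriples

#: Default class layers, herb to gene.
DEFAULT_LAYERS = (
    "Herb", "Disease", "Drug", "Target", "Protein", "EntrezID", "Gene",
)
#: Default properties connecting consecutive layers.
DEFAULT_PROPERTIES = (
    "treatment", "possibleDrug", "hasTarget",
    "hasAccession", "classifiedWith", "symbol",
)
#: Predicates reserved for distractor edges; never usable in a chain config.
DISTRACTOR_PREDICATES = ("geneSequence", "annotation", "xref")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic layered network.

    out_degree is the mean number of forward edges per entity (per-entity
    degrees are Poisson-like draws capped at the next layer's size);
    with injective=True every entity gets exactly one forward edge and no
    two entities in a layer share a successor, giving closed-form
    ground-truth counts. distractor_fraction f adds round(f/(1-f) * E)
    out-of-chain edges to a graph of E forward edges, so distractors make
    up fraction f of the final graph.
    """

    layer_sizes: tuple[int, ...] = (5, 5, 5, 5, 5, 5, 5)
    class_names: tuple[str, ...] = DEFAULT_LAYERS
    properties: tuple[str, ...] = DEFAULT_PROPERTIES
    out_degree: float = 1.5
    distractor_fraction: float = 0.0
    injective: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.properties) != len(self.layer_sizes) - 1:
            raise ValueError(
                f"{len(self.layer_sizes)} layers need "
                f"{len(self.layer_sizes) - 1} properties, "
                f"got {len(self.properties)}"
            )
        if len(self.class_names) != len(self.layer_sizes):
            raise ValueError("one class name per layer required")
        if any(n < 1 for n in self.layer_sizes):
            raise ValueError("every layer must hold at least one entity")
        if self.out_degree < 0:
            raise ValueError("out_degree must be >= 0")
        if not 0 <= self.distractor_fraction < 1:
            raise ValueError("distractor_fraction must lie in [0, 1)")
        overlap = set(self.properties) & set(DISTRACTOR_PREDICATES)
        if overlap:
            raise ValueError(f"chain properties clash with reserved distractors: {overlap}")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated graph, the chain it instantiates, and its reachability truth."""

    graph: TripleGraph
    rrc: ReasoningRuleChain
    ground_truth: frozenset[tuple[Resource, Resource]]
    config: GeneratorConfig = field(compare=False, default=None)  # type: ignore[assignment]


def _entity(class_name: str, index: int) -> Resource:
    return Resource(f"{class_name}_{index}")


def _sample_degree(rng: random.Random, mean: float, cap: int) -> int:
    """Poisson-like draw (sum of unit Bernoullis at fine granularity), capped."""
    if mean <= 0:
        return 0
    base = int(mean)
    extra = 1 if rng.random() < mean - base else 0
    return min(base + extra, cap)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Sample one layered network; identical config (incl. seed) ⇒ identical output."""
    rng = random.Random(config.seed)
    layers = [
        [_entity(name, i) for i in range(size)]
        for name, size in zip(config.class_names, config.layer_sizes)
    ]

    triples: list[Triple] = []
    # ground truth propagated layer by layer: entity -> set of layer-0 sources
    reaching: dict[Resource, set[Resource]] = {e: {e} for e in layers[0]}
    for depth, prop in enumerate(config.properties):
        sources, targets = layers[depth], layers[depth + 1]
        next_reaching: dict[Resource, set[Resource]] = {}
        if config.injective:
            if len(targets) < len(sources):
                raise ValueError("injective wiring needs non-shrinking layers")
            wiring = list(range(len(targets)))
            rng.shuffle(wiring)
            pairs = [(s, targets[wiring[i]]) for i, s in enumerate(sources)]
        else:
            pairs = []
            for s in sources:
                degree = _sample_degree(rng, config.out_degree, len(targets))
                for t in rng.sample(targets, degree):
                    pairs.append((s, t))
        for s, t in pairs:
            triples.append(Triple(s, prop, t))
            if s in reaching:
                next_reaching.setdefault(t, set()).update(reaching[s])
        reaching = next_reaching

    n_forward = len(triples)
    f = config.distractor_fraction
    n_distractor = round(f / (1 - f) * n_forward) if f else 0
    all_entities = [e for layer in layers for e in layer]
    for _ in range(n_distractor):
        s = rng.choice(all_entities)
        o = rng.choice(all_entities)
        p = rng.choice(DISTRACTOR_PREDICATES)
        triples.append(Triple(s, p, o))

    ground_truth = frozenset(
        (source, sink) for sink, sources in reaching.items() for source in sources
    )
    rrc = ReasoningRuleChain.from_properties(config.properties, config.class_names)
    return SyntheticDataset(
        graph=TripleGraph(triples),
        rrc=rrc,
        ground_truth=ground_truth,
        config=config,
    )


def scale_dataset(dataset: SyntheticDataset, factor: int) -> SyntheticDataset:
    """Disjoint union of ``factor`` isomorphic copies with fresh entity names.

    Copy r renames every entity Class_i to Class_(r*stride + i), where the
    stride clears the largest index in the base graph, so copies never
    share an entity. Rules are unchanged; ground truth is the union of the
    per-copy images, hence exactly factor times the base count.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return dataset

    def index_of(resource: Resource) -> tuple[str, int]:
        stem, _, idx = resource.identifier.rpartition("_")
        return stem, int(idx)

    stride = 1 + max(
        index_of(r)[1]
        for t in dataset.graph.triples
        for r in (t.subject, t.object)
    )

    def shift(resource: Resource, copy: int) -> Resource:
        stem, idx = index_of(resource)
        return Resource(f"{stem}_{copy * stride + idx}")

    triples = [
        Triple(shift(t.subject, r), t.predicate, shift(t.object, r))
        for r in range(factor)
        for t in dataset.graph.triples
    ]
    ground_truth = frozenset(
        (shift(s, r), shift(o, r))
        for r in range(factor)
        for s, o in dataset.ground_truth
    )
    config = dataset.config
    if config is not None:
        config = replace(
            config, layer_sizes=tuple(n * factor for n in config.layer_sizes)
        )
    return SyntheticDataset(
        graph=TripleGraph(triples),
        rrc=dataset.rrc,
        ground_truth=ground_truth,
        config=config,
    )


def verify_ground_truth(dataset: SyntheticDataset) -> bool:
    """Cross-check the generator's reachability against the brute-force oracle."""
    oracle = brute_force_associations(dataset.graph, rrc_to_pcs(dataset.rrc))
    return oracle == set(dataset.ground_truth)


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> tuple[Path, Path]:
    """Write graph.nt and ground_truth.tsv; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph_path = directory / "graph.nt"
    truth_path = directory / "ground_truth.tsv"
    write_ntriples(dataset.graph, graph_path)
    with open(truth_path, "w", encoding="utf-8") as handle:
        for source, sink in sorted(dataset.ground_truth):
            handle.write(f"{source.identifier}\t{sink.identifier}\n")
    return graph_path, truth_path
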