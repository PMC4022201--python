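# Methods

## Problem and model

The input is an instance triple graph G (assertions ⟨subject, predicate,
object⟩ over a linked biomedical network) and one or more reasoning rule
chains: ordered lists of class-level rules such as (Herb, treatment,
Disease), (Disease, possibleDrug, Drug), …, (EntrezID, symbol, Gene) whose
classes link end to end. Dropping the classes leaves the ordered property
list; the reasoner must materialize every pair (source, sink) connected in
G by a path that follows exactly that property sequence, labelling each
derived association with the composed chain property.

Formally, the ordered list of yet-uncomposed chain parts is the property
chain set (PCS); its elements are OWL property chains (OPCs), each one or
more primitive properties composed with the associative ⊗ operator. A
triple's PID is the position of its predicate in the current PCS, or −1
when the predicate does not occur there, in which case the triple is
invisible to the reasoner. Two triples at adjacent positions k, k+1 join
when the first's object equals the second's subject; the join emits
(subject_k, OPC_k ⊗ OPC_{k+1}, object_{k+1}). Reasoning reaches its
fixpoint when the PCS holds a single OPC; the triples bearing that OPC's
name are the associations.

The canonical name of an OPC is its components joined with `|`; primitive
property names may not contain `|` (validated at load), so the
serialization is reversible and collision-free. Literals may appear as
triple objects but never extend a path: no RDF triple can have a literal
subject, so a literal endpoint is always a dead end and is pruned at map
time.

## The three algorithms

All three run on a deterministic, single-process emulation of a
map/shuffle/reduce job: map every payload, group keyed emissions by exact
key equality, reduce each group in sorted key order, and collect a
passthrough channel for payloads that bypass the shuffle. Determinism
replaces the parallelism of a real cluster: outputs are invariant under any
permutation of the inputs, which the tests check directly. Join keys are
encoded `<chain_id>\x01<pid>\x01<resource>` with a control-character
separator, since entity labels routinely contain `_`.

**Naive.** Each iteration keys PID-0 triples on their object and PID-1
triples on their subject; each reduce group cross-products left subjects
with right objects under OPC₀ ⊗ OPC₁. PID ≥ 2 triples pass through
untouched; the PCS merges its first two elements. A length-N chain takes
exactly N−1 iterations regardless of the data. Unmatched PID-0/1 triples
die with their group: the next PCS would assign them PID −1 anyway, so
this only prunes dead-end paths early.

**Efficient (parity rule).** Joining all adjacent pairs naively is unsound
— a position-1 triple could join both leftward and rightward, yielding
fragments that never recombine. The Parity Judgment Rule resolves the
ambiguity: a triple at odd PID k keys on (k−1, subject), a triple at even
PID k on (k, object), so each group holds exactly one (even, odd) position
pair sharing one intermediate. After each pass the PCS halves (adjacent
pairs composed; an odd tail carried over), giving ⌈log₂N⌉ iterations. An
even-positioned OPC at the end of an odd-length PCS has no partner; its
triples bypass the shuffle and carry over unchanged — without this the
algorithm would be incorrect for every odd chain length, and it matches the
observable behaviour of the worked second iteration, where the composed
tail survives untouched. PIDs are recomputed from the current PCS each
iteration rather than decremented in place, so predicates absent from the
halved PCS drop out automatically.

**Multichain.** Several chains execute in shared iterated jobs. The mapper
evaluates every still-active chain against each triple and prefixes the
parity key with the chain id: a triple on the intersection of m chains
fans out to m keyed emissions, each landing in a reduce group private to
its chain. Iterations continue until the longest chain completes
(⌈log₂ max N⌉). A chain that finishes earlier parks its result triples in
a per-chain sink and contributes nothing to later iterations; letting its
finished triples keep circulating could corrupt no other chain (keys are
chain-scoped) but would waste work and complicate result collection.
Cross-chain deduplication of result sets is deliberately not performed.

A degenerate case handled conservatively throughout: a predicate occurring
at several PCS positions yields one emission per position, so repeated
properties (e.g. a chain p·p) self-join correctly.

## Oracle and ground truth

The brute-force oracle flattens the PCS to its primitive property sequence
and walks it with nested-loop joins, keeping only (source, endpoint) pairs
per frontier step. It shares no code with the engine or the reasoners, is
invariant under any re-bracketing of the chain, and is itself cross-checked
in the tests against a boolean adjacency-matrix product and a depth-first
path witness search. Storing endpoint pairs only (not full paths) keeps the
oracle linear in the number of reachable pairs rather than the number of
paths.

## Synthetic networks

The generator emulates the layered shape of an integrated herb-to-gene
network: one class per layer (default Herb, Disease, Drug, Target, Protein,
EntrezID, Gene, sizes 5 each), forward edges only between consecutive
layers, entity names `<Class>_<i>`. Defaults: `out_degree` 1.5 (per-entity
forward degree is ⌊d⌋ plus a Bernoulli remainder, capped at the next
layer's size — a realistic sparse, convergent wiring that exercises
many-to-one deduplication), `distractor_fraction` 0 (when f > 0,
round(f/(1−f)·E) extra edges with reserved out-of-chain predicates are
added to a graph of E forward edges, so distractors form fraction f of the
final graph). An `injective` switch wires each entity to exactly one
distinct successor, giving closed-form ground-truth counts for tests.
Ground truth is propagated layer by layer during generation — independently
of every reasoner — and is itself verified against the oracle. The same
seed reproduces the dataset byte-for-byte. `scale_dataset` builds factor
disjoint isomorphic copies under fresh entity indices, so association
counts scale exactly linearly while iteration counts stay fixed.

What the generator does not model: realistic biological degree
distributions (power laws, hubs), within-layer or backward edges, multiple
predicates between the same layer pair, or schema/TBOX emission. Passing
tests therefore demonstrate algorithmic correctness of chain composition on
layered graphs with noise, not robustness to arbitrary RDF topologies —
though nothing in the algorithms assumes layering, and the out-of-chain
distractor tests cover off-path edges in both directions.

## Evaluation metrics

`precision` = TP/(TP+FP) over a curated association sample; raises on an
empty sample rather than returning a sentinel. `speedup` = baseline time /
measured time for a scaled-up cluster; `sizeup` = measured time for m-fold
data / base time. The baseline is a designated configuration, not
necessarily one machine: for large inputs the smallest configuration able
to hold the data may already be a small cluster, and the formulas are
agnostic to that choice.

## Numerical and design choices

- Graphs have set semantics; duplicate assertions collapse on construction
  and two intermediate paths that converge produce one association.
- All iteration orders (graph traversal, reduce keys, serialization) are
  sorted, so every output is reproducible bit-for-bit.
- N-Triples I/O delegates parsing and term formatting to rdflib; bare
  labels are minted under `urn:kgchain:` on write and stripped on read, so
  worked-example graphs round-trip while foreign IRIs survive verbatim.
  The writer emits sorted statements itself to guarantee deterministic
  files.
- Problem sizes in the test suite and the acceptance script are desk-scale
  (layers of ≤ 20 entities, 200-graph validation sweeps): the algorithms'
  guarantees — iteration counts, oracle equality — are size-independent,
  so small graphs prove the same properties that a cluster-scale run would.

## Known limitations

- Single-process execution only; mapper/reducer counts, data partitioning,
  fault tolerance and HDFS semantics of a real cluster are out of scope.
- Only property chains are modelled: no OWL class expressions, inverse or
  symmetric properties, or subsumption.
- The naive reasoner's early pruning discards unmatched head-of-chain
  triples; identical results, but intermediate graphs differ from a
  strictly literal replay of the update rule.
- Wall-clock scalability (speedup/sizeup) is provided as formulas over
  supplied timings; the package does not instrument clusters.
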