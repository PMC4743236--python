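# Methods

This note documents the model semantics, the numerical and design choices
behind `nrbnkit`, and what the shipped synthetic inputs do and do not
represent.

## Model and update semantics

A regulatory network is a directed graph of binary genes; gene `v` carries
a Boolean function over an *ordered* regulator list.  Truth tables are
indexed with the first-listed regulator as the most significant bit — any
consistent convention works, but one must be fixed for file-format
round-trips, and this one is used everywhere (tables, state encodings,
canonical attractor rotations).  Updates are synchronous and
deterministic.  Zero-input genes are allowed as constants (table of length
one): augmentation and knockout clamping can strand genes without
regulators.  Self-loops are accepted (a gene may regulate itself);
multi-edges are impossible by construction since a regulator may appear
only once per function.

Knockouts and knock-ins are *clamps*: per-gene forced values applied after
every update, layered over the untouched wild-type function so a
perturbation is reversible.  The simulator encodes states as uint8
vectors; one synchronous step is a sparse matrix–vector product that
computes every gene's table row index at once, so stepping is O(edges)
regardless of N (networks of a few thousand genes are practical).

## Attractor search

Exhaustive search enumerates all 2^N initial states (refused above N = 20
by default); sampled search draws initial states uniformly *with*
replacement — the only reading that scales to large N — with a
without-replacement option for small networks.  Every state visited on a
resolved trajectory is cached against its attractor, so later trajectories
stop at first contact with anything seen before; this makes the 500-sample
searches on 200-gene networks take seconds.  Trajectories that neither
close nor touch a known state within `max_steps` (default 1000, the
conventional horizon for dynamics of this class) are counted as
unresolved and logged, never dropped; an atlas can legitimately be empty
if the network's cycles are longer than the horizon, and every downstream
consumer treats that as "undetermined", not as an error.

Attractors are canonicalised by rotating the cycle to start at its
smallest encoded state and atlases are sorted by (length, canonical
states), so attractor ids are stable and independent of discovery order.
Attractor "robustness" is exposed as the ATM diagonal (self-transition
probability) rather than as a separate statistic.

## Flips and the attractor transition matrix

A flip inverts one gene and holds the inverted value for `duration`
synchronous steps (override semantics — the gene's function is suspended
for the hold, which is what makes durations larger than one meaningful);
all other genes update normally, and relaxation starts from the release
state.  The ATM is built by flipping, by default, *every* gene in *every*
phase of every attractor — exact enumeration rather than sampling, since
the relaxations are deterministic; phase and target sampling are available
for large networks and are used by the batch sessions.

A flip from a sampled (hence incomplete) atlas can land in an attractor
the atlas missed.  The default is to append the new attractor (with a
warning) and to give it flip rows of its own, so the matrix stays square
and row-stochastic; a strict mode counts such experiments as unresolved
instead.  Extension is capped (default 200 new attractors) to bound the
quadratic growth on pathological networks.

## TES decomposition and differentiation trees

Thresholding removes ATN edges with probability strictly below δ, so δ = 0
removes nothing.  TESs are formalised as the *terminal* strongly connected
components of the pruned ATN: sets the dynamics can wander within but not
escape.  Attractors in non-terminal components are transient at that
threshold.  Two useful facts hold exactly and are property-tested: along
an increasing sweep each TES refines into some lower-threshold TES up to
transients, and the TES count never decreases.

Trees are assembled across consecutive sweep levels by attractor-set
inclusion.  A TES identical at two consecutive levels persists as one node
(no unary chains).  A re-entrant transient — an attractor that was
transient at a low threshold and becomes its own terminal component once
its escape edge is pruned — violates strict refinement; such a TES is
attached to the parent with maximal overlap and the event is logged.  If
the first sweep level is already split the forest is stitched under a
virtual root and flagged.  Auto level sets are the sorted distinct
off-diagonal transition probabilities with 0 and 1 as sentinels.

Tree comparison uses only the shape table n_x(k,l) (nodes at depth l with
k children); labels and attractor annotations never enter the distance.
Depth here is graph depth from the root (root = level 0).  The
representative tree samples increasing threshold combinations anchored at
the smallest auto level, groups the resulting trees by shape table, and
returns the mode; ties break toward fewer nodes, then the
lexicographically smaller shape signature.  Ensemble matching enumerates
combinations exhaustively when their number fits the per-network budget
and samples otherwise; budget exhaustion without a hit marks the network
*undetermined* rather than unmatched, and atlases that are empty or exceed
the attractor cap (default 64) are likewise undetermined — a screen never
silently matches or rejects a network it could not afford to analyse.

## Generation and augmentation

Topologies: fixed in-degree, Erdős–Rényi (exact edge count, drawn without
replacement in the dense regime and by rejection in the sparse regime),
preferential attachment (undirected skeleton, each edge then oriented
uniformly at random), power-law (per-gene in-degree from a truncated
discrete power law, so the total edge count is stochastic under this
mode), and Watts–Strogatz small world.  For the small-world graph both
orientations of each undirected edge are included, so with rewiring
probability 0 the *directed* ring lattice is returned exactly — random
orientation would have broken that exactness, which we consider the more
useful contract; preferential attachment keeps random orientation since no
analogous exactness is at stake.

Function schemes: *bias-random* (each table bit is 1 with probability
`bias`), *canalyzing* (one input/value pair forces the output, remaining
rows bias-random; a canalyzing inhibitor constructor models miRNA-style
repressors that force their target off), and *logic* (random AND/OR/NOT
expressions over all regulators, compiled to tables).  Named regime
presets follow the classical (K, bias) settings: ordered (2, 0.3),
critical (2, 0.5), chaotic (3, 0.5); a second chaotic variant (3, 0.3)
also circulates and is exposed as `chaotic-low-bias`.

Augmentation grows a core to exact target node and edge counts.  New edges
may connect new↔new, new↔core and core→new, but never core→core — the
core's internal wiring is inviolate; a flag additionally protects core
genes from gaining regulators at all.  When a core gene does gain inputs,
its function is extended by the *duplicate-then-bias* policy: the table is
replicated across the new-input combinations and rows with any new input
active are resampled at the configured bias, so behaviour with all new
inputs off equals the original function exactly (a *silent* policy keeps
pure replication).  Ensembles derive per-network seeds from a master seed
via seed sequences, making whole ensembles byte-reproducible.

## Robustness statistics

The avalanche of a perturbation is the number of genes whose activation
pattern differs between the perturbed and wild-type attractors reached
from the same initial state.  Frozen-vs-frozen genes compare by value.
Equal-length cycles are aligned under the global cyclic rotation
minimising total Hamming mismatch (smallest rotation index on ties) —
alignment must be pinned for determinism.  Unequal lengths count a gene as
affected unless its pattern is constant and equal in both.  Sensitivity
counts, per gene, the experiments whose avalanche contains it; the
conservation identity Σ_v sensitivity(v) = Σ_e avalanche(e) is exact.
Both a single-initial-state protocol (`avalanche`,
`run_perturbation_experiments`) and the attractor-level protocol used by
the knockout tree screen are exposed; the screen re-runs atlas → ATM →
best tree per silenced gene and reports the d̂ distribution.

Classical measures: global clustering (transitivity of the undirected
skeleton); diameter and average path length over directed paths within the
largest weakly connected component, with unreachable ordered pairs
excluded and counted.

## Synthetic inputs, scales, and what the tests show

The shipped 40-gene / 51-interaction core is *synthetic*: an Erdős–Rényi
wired, bias-0.5 network regenerated from a fixed seed.  It reproduces the
size and the ensemble statistics of a curated signalling core, not any
real wiring, so tests passing on it demonstrate that the machinery
(augmentation bookkeeping, simulation, screening) is correct — they say
nothing about the biology of any particular pathway.  The hematopoietic
differentiation tree (MPP → CMP/CLP → MEP/GMP/B-progenitor/T-NK-progenitor
→ mature cells, 14 nodes) is transcribed from the standard hematopoiesis
scheme; the assignment MEP→{EC, MK} and GMP→{M, N/E/B} is the conventional
one and is curator-supplied.

Ensemble experiments in the test suite run at desk scale chosen once:
augmented networks of 200 genes / 400 edges (mean connectivity 2, bias
0.5 — the classical critical-regime settings for studies of this kind),
500 sampled initial states for the byte-stability session over 20
networks, and 200 samples for the 60-network screening session.  Screening
outcomes (how many networks match a target tree at tolerance 0) are
realisation-dependent and are deliberately never asserted; the suite
asserts the protocol runs end to end, the accounting identities hold
exactly, and reruns are byte-identical.

## Known limitations

* Asynchronous or probabilistic update schedules, multi-valued logic and
  ODE semantics are out of scope.
* Attractor search is simulation-based; no SAT/BDD symbolic detection, so
  attractors with basins far below the sampling density, or cycles longer
  than `max_steps`, can be missed (and are then reported as unresolved or
  as later ATM extensions).
* Only single-gene flips are modelled, matching the NRBN noise model; no
  simultaneous multi-gene perturbations.
* Tree comparison is shape-based by design; it cannot distinguish trees
  that differ only in which attractors sit where.
* SBML Qual import/export is detected and refused rather than supported.
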