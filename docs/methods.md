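# Methods

## Problem and data model

The input is a set of predicted subcomponents — PDB files of 2–3 chains with
per-residue plDDT in the B-factor column of the Cα atom — plus the unique
chain sequences (FASTA) and the stoichiometry (copies per unique sequence).
The in-memory model is deliberately reduced to what the assembly predicates
need: per residue, the Cα and Cβ positions (Cβ = Cα for glycine) and the
plDDT. Residues without a Cα are dropped on read; all interface, overlap and
clash rules operate on resolved residues only, so gaps in numbering are
tolerated and superposition uses the residue-index intersection of the
shared chain (at least 3 common residues required).

## Geometric rules

Three distance predicates, with deliberate boundary conventions:

| rule | atoms | threshold | boundary |
|---|---|---|---|
| interface contact | Cβ (Cα for Gly) | 8 Å | inclusive (≤) |
| interaction | Cβ | ≥ 10% of the shorter chain's Cβs within 8 Å | inclusive |
| overlap (path discontinued) | Cα | > 50% of the shorter chain within 5 Å | strict > |
| clash (reported only) | all stored atoms | 1 Å | strict < |

At 3-decimal PDB coordinate precision the measure of the boundary set is
zero, so the inclusive/strict choices matter only for constructed tests;
they are fixed here so every downstream count is reproducible. Clashes are
counted over the stored atom set (Cα and Cβ per residue); an accepted
placement with sub-1 Å clashes but no overlap is kept as-is and the clash
count reported, since the overlap rule is the assembly-rejection criterion.

Neighbour queries use a dense numpy distance matrix for small chains and a
KD-tree above 250 k point pairs; both routes are contractually identical to
the brute-force double loop and are tested against it.

Superposition is SVD-based least squares (Kabsch with reflection
correction) on Cα atoms of the shared chain only — Cα-only is robust to
missing side-chain atoms in predictions. Configurations with fewer than 3
points or (near-)collinear geometry are rejected, since the rotation is
undefined there.

## Interaction network and path complexity

Each subcomponent contributes one edge per interacting chain pair, so a
trimer acts as its three dimers. Edges with identical sequence pairs from
different subcomponents are retained as distinct alternative conformations —
a single predicted dimer conformation per pair is often insufficient for
ring-like homomers, which is exactly why trimeric subcomponents are used.
An optional allowed-pair list restricts edges to known interactions (guided
mode). The combinatoric helpers give D(n) = n(n−1)/2 dimers,
T(n) = n(n−1)(n−2)/6 trimers, 3·T(n) edges from all trimers, and the
spanning-path bound P(n′) = n′^(n′−2) in exact integer arithmetic (Cayley's
labeled-tree count; ~2.3·10⁴¹ at n′ = 30).

## Search

Monte Carlo tree search with UCB = V̄ᵢ + 2√(ln N / nᵢ); V̄ᵢ is the mean of
backpropagated scores below node i, and unvisited children score +∞ so each
sibling is tried once before any is revisited (ties break to the lowest
action index, keeping the search deterministic). Expansion creates *all*
applicable children of a leaf: an edge S1–S2 applies from a placed anchor of
S1 when an unplaced copy of S2 remains, the same (anchor, edge, direction)
has not already been used on the path, and the placement passes the overlap
check. Rollouts try candidate placements in uniformly random order and stop
only when every remaining candidate is rejected or the complex is complete.

Design choices made where the procedure was genuinely open:

* **Score normalization.** Raw complex scores grow with chain count and
  would swamp the exploration constant 2, so backpropagated scores are
  divided by the running maximum observed raw score (V̄ᵢ ∈ [0,1]).
  Configurable: `raw`, `running_max` (default), `fixed`.
* **Restarts.** The start chain is arbitrary; a single random root can
  strand the search in a poorly connected corner of the network, so by
  default one tree is grown per unique sequence (deterministically seeded
  from the master seed) and the best result kept. `restarts="single"`
  picks one random root.
* **Copy symmetry.** Unplaced copies of the same sequence are
  interchangeable; the lowest-index copy is always instantiated, avoiding a
  factorial blow-up of equivalent branches in homomers.
* **Result selection.** The most-supported path (descent by visit count,
  ties by mean value) is computed per restart; the best simulated terminal
  state (by completeness, then score) is retained alongside, and the
  better of the two is returned. Both are exposed on the result object.
* **Budgets.** Default 10 000 iterations with early stop after 500
  iterations without improvement, plus an optional wall-clock budget; all
  configurable. Searches that exhaust the budget return the best state
  found, flagged incomplete.

Identical seed, config and inputs give bit-identical assemblies, reports
and logs; all randomness derives from one master seed via spawned
`SeedSequence`s.

## Scoring and mpDockQ

Per placed chain: n = pooled Cβ–Cβ contacts (≤ 8 Å) against all partners
simultaneously (the multiple-interface DockQ convention), p̄ = mean plDDT
over the chain's own residues participating in ≥ 1 contact, term = p̄·log₁₀ n.
A zero-contact chain contributes 0 (log₁₀ 0 is undefined, and an unsupported
chain should add no confidence; this also lets partial assemblies be scored
without special cases). The interface average is per-residue, not per-pair —
the natural reading of the multiple-interface treatment; the alternative
denominator would weight residues by their contact multiplicity. Note each
contact pair appears in both partners' terms, i.e. effectively twice in the
complex sum — the score is summed "for all interfaces and chains".

mpDockQ(x) = L/(1+e^(−k(x−x₀))) + b with defaults L = 0.728, x₀ = 309.375,
k = 0.098, b = 0.262 — the published calibration of this score against
TM-scores of trimer-based assemblies. It is strictly increasing and bounded
in (b, L+b); `fit_mpdockq` refits all four parameters by nonlinear least
squares (scipy `curve_fit`, data-driven initial guess) and rejects
degenerate inputs (constant x or constant accuracy). ROC curves sweep all
distinct score thresholds (ties share a threshold), TPR = TP/(TP+FN),
FPR = FP/(FP+TN), AUC by trapezoid; this hand implementation is
cross-checked in tests against Mann–Whitney pair counting and
scikit-learn.

## Synthetic fixtures

The generator fabricates ground-truth complexes from one idealized chain
template: a spherical-spiral Cα trace (24 residues on a 6 Å sphere, ~4 Å
consecutive spacing) with Cβ pseudo-atoms offset 1.5 Å radially outward —
a compact, roughly isotropic blob that packs like a sphere. Chain centroids
sit 16.5 Å apart, chosen once so that adjacent chains have comfortable
Cβ-contact interfaces (well above the 10% interaction threshold) while
staying clash-free and far from the overlap limit. Arrangements: cyclic
(n-fold rotation about z; rotating by 2π/n maps chain i onto i+1 exactly),
dihedral (two counter-rotated stacked rings related by a two-fold axis, ring
offset half a step so each chain touches two neighbours in each ring),
linear tree (a path with golden-angle twists; the unique-spanning-path
regime), and asymmetric (random sequential packing with a connected contact
graph). Generated truths are validated: connected adjacency, no overlap
violations, no clashes.

Slicing emulates how predictors are queried: native dimers/trimers keep
adjacent pairs / connected triples, all-trimers keeps every 3-subset; groups
are deduplicated by sorted seq-id tuple, since predictions are made per
unique sequence combination. This reproduces a real failure mode: a
homomeric complex with two distinct interface types collapses to a single
retained subcomponent and cannot be completed — hence the dihedral
end-to-end fixture is heteromeric while the cyclic one is homomeric (one
interface type suffices for a ring). Subcomponents are re-centred, optionally
perturbed with iid isotropic Gaussian coordinate noise per atom, and given
synthetic plDDT (constant 90 by default, or an interface-distance decay
model). Corruption operators emulate reported prediction pathologies:
dropped interface files, injected sub-1 Å clashes, and rotated
("wrong-conformation") interfaces that still pass the interaction test.

What passing these fixtures does *not* show: robustness to real predictor
error, which is structured (inter-chain orientation error, correlated
plDDT), not iid Gaussian; nor physical plausibility of interfaces.
The fixtures exercise the bookkeeping, geometry and search logic exactly,
and the noise ladder (σ ∈ {0, 0.2, 0.5, 1} Å) checks that recovery error
degrades gracefully in expectation.

## Reference comparison

External structure-alignment tools are not used; assemblies are evaluated
against synthetic ground truth by chain-mapped Cα-RMSD: over sequence-
compatible chain bijections, the mapping minimizing the RMSD after joint
superposition. Up to 720 mappings (6 copies of a sequence) the search is
exhaustive; above that, a seed-pair superposition followed by Hungarian
assignment on a per-chain cost matrix, iterated with re-superposition to a
fixed point, is used (exact on all fixtures tested against the exhaustive
route). RMSD is rigid-motion invariant, so assemblies are compared in
whatever frame the search produced.

## Problem sizes and numerics

The test suite and acceptance script run fixtures of 3–12 chains of 24
residues with search budgets of 80–500 iterations and early stopping —
sizes at which the end-to-end recoveries are exact (Cα-RMSD ~1e-14 at
σ = 0) and the exhaustive path enumeration used as an optimality oracle
stays feasible. Defaults for real use are higher (10 000 iterations).
Floating-point conventions: PDB coordinates round-trip at 3 decimals and
B-factors at 2; sigmoid evaluation clamps the exponent at ±700 to avoid
overflow; strict-monotonicity claims for mpDockQ are asserted on
x ∈ [0, 500], beyond which successive double-precision values of the upper
tail become indistinguishable.

## Known limitations

* Stoichiometry must be supplied; it is not inferred.
* Only plain PDB input (≤ 62 chains per file); mmCIF, ligands, nucleic
  acids and altloc handling beyond the first conformation are out of scope.
* No refinement or clash repair of assembled models.
* TM-score-based evaluation against experimental structures requires
  external alignment tools and is out of scope; the RMSD evaluator assumes
  a known chain-sequence correspondence.
* The mpDockQ default parameters are a published calibration against real
  predictor outputs; scores on synthetic fixtures use the same formula but
  their absolute confidence values should not be over-interpreted.
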