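"""Assembly actions: place chains by superposition, reject overlaps, orchestrate runs.

The elementary move: if interfaces A-B and B-C were predicted, A-B-C is built
by superposing the copy of B inside the B-C subcomponent onto the placed B
(CA atoms, residue-index intersection) and carrying C along with the fitted
transform. A placement that overlaps any placed chain (over half of the
shorter chain's CAs within 5 A) is rejected and the path is discontinued
through that edge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import permutations
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import geometry, scoring, structio
from .network import InteractionEdge, InteractionNetwork, build_network
from .structio import ChainStructure, Subcomponent

logger = logging.getLogger(__name__)

MIN_COMMON_RESIDUES = 3

Instance = tuple[str, int]  # (seq_id, copy index)


class AssemblyError(ValueError):
    pass


class PathStep(NamedTuple):
    edge_index: int
    anchor: Instance
    new_instance: Instance
    direction: int  # which element of edge.chain_pair is the anchor-side chain
    anchor_rmsd: float


class Action(NamedTuple):
    """A candidate move: apply one edge from a placed anchor in one direction."""

    edge_index: int
    anchor: Instance
    direction: int


def _interface_term(chain: ChainStructure, n_contacts: int,
                    contact_res: frozenset[int]) -> float:
    if n_contacts == 0:
        return 0.0
    pb = chain.plddt_by_index
    avg = sum(pb[i] for i in contact_res) / len(contact_res)
    return avg * np.log10(n_contacts)


@dataclass(frozen=True)
class AssemblyState:
    """Immutable partial assembly: placed chains in the world frame plus the path.

    ``iface`` caches per-chain pooled interface bookkeeping (contact count and
    the chain's own contacting residue indices) so the complex score updates
    incrementally; it always agrees with a full rescoring of the coordinates.
    """

    placed: dict[Instance, ChainStructure]
    path: tuple[PathStep, ...]
    stoichiometry: dict[str, int]
    score: float
    used: frozenset[tuple[Instance, int, int]] = frozenset()
    iface: dict[Instance, tuple[int, frozenset[int]]] = field(default_factory=dict)

    @property
    def n_placed(self) -> int:
        return len(self.placed)

    @property
    def remaining(self) -> dict[str, int]:
        placed_per_seq: dict[str, int] = {}
        for sid, _ in self.placed:
            placed_per_seq[sid] = placed_per_seq.get(sid, 0) + 1
        return {sid: cnt - placed_per_seq.get(sid, 0)
                for sid, cnt in self.stoichiometry.items()}

    @property
    def is_complete(self) -> bool:
        return self.n_placed == sum(self.stoichiometry.values())

    @property
    def completeness(self) -> float:
        return scoring.completeness(self.n_placed, self.stoichiometry)

    def chains(self) -> list[ChainStructure]:
        return list(self.placed.values())


def initial_state(network: InteractionNetwork, subs: dict[str, Subcomponent],
                  root_seq: str) -> AssemblyState:
    """Single-chain state seeding the search at copy 0 of ``root_seq``.

    The seed chain keeps the local coordinates of the first subcomponent that
    contains its sequence; the assembly is only defined up to a global rigid
    motion anyway.
    """
    if root_seq not in network.stoichiometry:
        raise AssemblyError(f"unknown root seq_id {root_seq!r}")
    for name in sorted(subs):
        for c in subs[name].chains:
            if c.seq_id == root_seq:
                seed = c.renamed(c.chain_id)
                return AssemblyState({(root_seq, 0): seed}, (),
                                     dict(network.stoichiometry), 0.0,
                                     iface={(root_seq, 0): (0, frozenset())})
    raise AssemblyError(f"no subcomponent contains seq_id {root_seq!r}")


def applicable_actions(state: AssemblyState, network: InteractionNetwork) -> list[Action]:
    """Candidate moves before the overlap check, in deterministic order.

    An edge S1-S2 is applicable from a placed anchor of seq S1 when an
    unplaced copy of S2 remains and the identical (anchor, edge, direction)
    placement has not been used on this path. Unplaced copies of the same
    seq_id are interchangeable; the lowest-index copy is instantiated.
    """
    remaining = state.remaining
    anchors = sorted(state.placed)
    out: list[Action] = []
    for ei, edge in enumerate(network.edges):
        s1, s2 = edge.seq_pair
        for direction, (anchor_seq, new_seq) in enumerate(((s1, s2), (s2, s1))):
            if remaining.get(new_seq, 0) < 1:
                continue
            for anchor in anchors:
                if anchor[0] != anchor_seq:
                    continue
                if (anchor, ei, direction) in state.used:
                    continue
                out.append(Action(ei, anchor, direction))
    return out


def _lowest_unplaced_copy(state: AssemblyState, seq_id: str) -> int:
    placed = {idx for sid, idx in state.placed if sid == seq_id}
    for i in range(state.stoichiometry[seq_id]):
        if i not in placed:
            return i
    raise AssemblyError(f"no unplaced copy of {seq_id!r}")


def add_chain(state: AssemblyState, edge: InteractionEdge, anchor: Instance,
              subs: dict[str, Subcomponent], direction: int = 0,
              edge_index: int = -1) -> AssemblyState | None:
    """Apply one edge: superpose the subcomponent onto the anchor, place the new chain.

    Returns the extended state, or None when the placement is rejected (new
    chain overlaps a placed chain, or too few common residues to superpose).
    Contract violations (anchor seq mismatch) raise.
    """
    sub = subs[edge.source_sub]
    anchor_chain = sub.chain(edge.chain_pair[direction])
    new_chain = sub.chain(edge.chain_pair[1 - direction])
    if anchor_chain.seq_id != anchor[0]:
        raise AssemblyError(
            f"anchor {anchor} does not match edge endpoint seq {anchor_chain.seq_id!r}"
        )
    placed_anchor = state.placed[anchor]

    # superpose on the residue-index intersection of the shared chain
    common = np.intersect1d(placed_anchor.residue_indices, anchor_chain.residue_indices)
    if common.size < MIN_COMMON_RESIDUES:
        return None
    sel_fixed = np.isin(placed_anchor.residue_indices, common)
    sel_mobile = np.isin(anchor_chain.residue_indices, common)
    try:
        transform, rmsd = geometry.superpose(placed_anchor.ca_coords[sel_fixed],
                                             anchor_chain.ca_coords[sel_mobile])
    except geometry.GeometryError:
        return None

    placed_new = new_chain.transformed(transform.rotation, transform.translation)
    for other in state.placed.values():
        if geometry.is_overlap(placed_new, other):
            return None

    new_instance = (new_chain.seq_id, _lowest_unplaced_copy(state, new_chain.seq_id))
    placed = dict(state.placed)
    placed[new_instance] = placed_new

    # incremental interface bookkeeping: only chains touching the newcomer change
    iface = dict(state.iface)
    n_new, res_new = 0, set()
    for key, other in state.placed.items():
        pairs = geometry.interface_contacts(placed_new, other)
        if not pairs:
            continue
        n_o, r_o = iface.get(key, (0, frozenset()))
        iface[key] = (n_o + len(pairs), r_o | frozenset(j for _, j in pairs))
        n_new += len(pairs)
        res_new.update(i for i, _ in pairs)
    iface[new_instance] = (n_new, frozenset(res_new))
    score = float(sum(_interface_term(placed[k], *iface[k]) for k in placed))

    step = PathStep(edge_index, anchor, new_instance, direction, rmsd)
    return AssemblyState(
        placed,
        state.path + (step,),
        state.stoichiometry,
        score,
        state.used | {(anchor, edge_index, direction)},
        iface,
    )


def apply_action(state: AssemblyState, action: Action,
                 network: InteractionNetwork,
                 subs: dict[str, Subcomponent]) -> AssemblyState | None:
    return add_chain(state, network.edges[action.edge_index], action.anchor,
                     subs, action.direction, edge_index=action.edge_index)


def state_has_overlap(state: AssemblyState) -> bool:
    """Post-hoc audit: does any placed pair violate the overlap predicate?"""
    chains = state.chains()
    return any(
        geometry.is_overlap(a, b)
        for i, a in enumerate(chains) for b in chains[i + 1:]
    )


# --- end-to-end orchestration ----------------------------------------------

def load_subcomponents(sub_dir: str | Path, sequences: dict[str, str]
                       ) -> list[Subcomponent]:
    """Read every PDB in a directory and assign its chains to sequence records."""
    sub_dir = Path(sub_dir)
    files = sorted(sub_dir.glob("*.pdb"))
    if not files:
        raise AssemblyError(f"no .pdb files in {sub_dir}")
    subs = []
    for f in files:
        chains = structio.read_structure(f)
        if not 2 <= len(chains) <= 3:
            logger.warning("%s: %d chains, skipping (subcomponents are 2-3 chains)",
                           f.name, len(chains))
            continue
        assignment = structio.assign_sequences(chains, sequences)
        subs.append(Subcomponent(f.stem, chains, assignment))
    if not subs:
        raise AssemblyError(f"no usable 2-3 chain subcomponents in {sub_dir}")
    return subs


def assemble(sub_dir: str | Path, fasta: str | Path, stoichiometry,
             config=None, out_dir: str | Path | None = None,
             allowed_pairs: set[frozenset[str]] | None = None):
    """Full pipeline: read subcomponents, build the network, search, write outputs.

    Returns (SearchResult, ScoreReport). With ``out_dir`` set, writes
    assembly.pdb, chain_map.tsv, report.json, path_trace.json and
    search_log.jsonl.
    """
    from .mcts import SearchConfig, run_search

    if config is None:
        config = SearchConfig()
    sequences = structio.read_fasta(fasta)
    stoich = structio.parse_stoichiometry(stoichiometry)
    unknown = set(stoich) - set(sequences)
    if unknown:
        raise AssemblyError(f"stoichiometry names unknown seq_ids: {sorted(unknown)}")
    subs = load_subcomponents(sub_dir, sequences)
    net = build_network(subs, stoich, allowed_pairs=allowed_pairs)
    result = run_search(net, {s.name: s for s in subs}, stoich, config)

    state = result.state
    labels = [f"{sid}_{idx}" for sid, idx in sorted(state.placed)]
    chains = [state.placed[k] for k in sorted(state.placed)]
    report = scoring.score_report(chains, stoich, labels=labels)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ids = structio.PDB_CHAIN_IDS
        renamed = [c.renamed(ids[i]) for i, c in enumerate(chains)]
        structio.write_structure(renamed, out_dir / "assembly.pdb")
        with open(out_dir / "chain_map.tsv", "w") as fh:
            fh.write("chain_id\tseq_id\tcopy\n")
            for i, key in enumerate(sorted(state.placed)):
                fh.write(f"{ids[i]}\t{key[0]}\t{key[1]}\n")
        report.to_json(out_dir / "report.json")
        trace = {
            "complete": state.is_complete,
            "completeness": state.completeness,
            "total_score": state.score,
            "seed": config.seed,
            "steps": [
                {"edge_index": s.edge_index, "anchor": list(s.anchor),
                 "new_instance": list(s.new_instance), "direction": s.direction,
                 "anchor_rmsd": s.anchor_rmsd}
                for s in state.path
            ],
        }
        (out_dir / "path_trace.json").write_text(json.dumps(trace, indent=2))
        with open(out_dir / "search_log.jsonl", "w") as fh:
            for entry in result.log:
                fh.write(json.dumps(entry) + "\n")
        if not state.is_complete:
            logger.warning("assembly incomplete: %d/%d chains placed",
                           state.n_placed, sum(stoich.values()))
    return result, report


# --- reference comparison ---------------------------------------------------

EXHAUSTIVE_MAPPING_LIMIT = 720  # permutations per seq group (6!)


def _grouped(chains: list[ChainStructure]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(chains):
        if c.seq_id is None:
            raise AssemblyError(f"chain {c.chain_id} lacks a seq_id; assign sequences first")
        groups.setdefault(c.seq_id, []).append(i)
    return groups


def _mapping_rmsd(model: list[ChainStructure], reference: list[ChainStructure],
                  mapping: dict[int, int]) -> float:
    fixed, mobile = [], []
    for mi, ri in mapping.items():
        m, r = model[mi], reference[ri]
        common = np.intersect1d(m.residue_indices, r.residue_indices)
        if common.size == 0:
            return float("inf")
        fixed.append(r.ca_coords[np.isin(r.residue_indices, common)])
        mobile.append(m.ca_coords[np.isin(m.residue_indices, common)])
    fixed = np.vstack(fixed)
    mobile = np.vstack(mobile)
    try:
        _, rmsd = geometry.superpose(fixed, mobile)
    except geometry.GeometryError:
        return float("inf")
    return rmsd


def evaluate_against_reference(model: list[ChainStructure],
                               reference: list[ChainStructure]
                               ) -> tuple[dict[int, int], float]:
    """Best chain mapping (model index -> reference index) and CA-RMSD after it.

    Small seq groups are matched exhaustively; larger homomeric groups use
    seed-pair superposition followed by Hungarian assignment on a chain-chain
    RMSD cost matrix, iterated to a fixed point. RMSD is rigid-motion
    invariant, so a model equal to the reference under any global motion
    scores 0.
    """
    if not model or not reference:
        raise AssemblyError("both model and reference must be non-empty")
    if len(model) > len(reference):
        raise AssemblyError("model has more chains than the reference")
    mg, rg = _grouped(model), _grouped(reference)
    for sid, idxs in mg.items():
        if len(rg.get(sid, [])) < len(idxs):
            raise AssemblyError(f"reference lacks enough copies of seq_id {sid!r}")

    import math
    n_mappings = 1
    for sid, idxs in mg.items():
        n_mappings *= math.perm(len(rg[sid]), len(idxs))
    if n_mappings <= EXHAUSTIVE_MAPPING_LIMIT:
        best: tuple[dict[int, int], float] | None = None
        seqs = sorted(mg)
        def rec(i: int, mapping: dict[int, int]):
            nonlocal best
            if i == len(seqs):
                r = _mapping_rmsd(model, reference, mapping)
                if best is None or r < best[1]:
                    best = (dict(mapping), r)
                return
            sid = seqs[i]
            for perm in permutations(rg[sid], len(mg[sid])):
                for mi, ri in zip(mg[sid], perm):
                    mapping[mi] = ri
                rec(i + 1, mapping)
                for mi in mg[sid]:
                    del mapping[mi]
        rec(0, {})
        assert best is not None
        return best

    return _hungarian_mapping(model, reference, mg, rg)


def _hungarian_mapping(model, reference, mg, rg) -> tuple[dict[int, int], float]:
    best: tuple[dict[int, int], float] | None = None
    seed_seq = max(mg, key=lambda s: len(mg[s]))
    m0 = mg[seed_seq][0]
    for r0 in rg[seed_seq]:
        try:
            common = np.intersect1d(model[m0].residue_indices,
                                    reference[r0].residue_indices)
            t, _ = geometry.superpose(
                reference[r0].ca_coords[np.isin(reference[r0].residue_indices, common)],
                model[m0].ca_coords[np.isin(model[m0].residue_indices, common)])
        except geometry.GeometryError:
            continue
        moved = [c.transformed(t.rotation, t.translation) for c in model]
        mapping: dict[int, int] = {}
        for _ in range(3):  # assignment / re-superposition fixed point
            mapping = {}
            for sid in mg:
                cost = np.array([
                    [np.linalg.norm(moved[mi].ca_coords.mean(0)
                                    - reference[ri].ca_coords.mean(0))
                     for ri in rg[sid]] for mi in mg[sid]])
                rows, cols = linear_sum_assignment(cost)
                for r_i, c_i in zip(rows, cols):
                    mapping[mg[sid][r_i]] = rg[sid][c_i]
            rmsd = _mapping_rmsd(model, reference, mapping)
            fixed, mobile = [], []
            for mi, ri in mapping.items():
                common = np.intersect1d(model[mi].residue_indices,
                                        reference[ri].residue_indices)
                fixed.append(reference[ri].ca_coords[
                    np.isin(reference[ri].residue_indices, common)])
                mobile.append(model[mi].ca_coords[
                    np.isin(model[mi].residue_indices, common)])
            try:
                t, _ = geometry.superpose(np.vstack(fixed), np.vstack(mobile))
            except geometry.GeometryError:
                break
            moved = [c.transformed(t.rotation, t.translation) for c in model]
        if best is None or rmsd < best[1]:
            best = (mapping, rmsd)
    if best is None:
        raise AssemblyError("no seq-compatible chain mapping could be superposed")
    return best
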