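"""Monte Carlo tree search over assembly paths.

Each tree node is a partial assembly; children apply one interaction edge via
superposition. The four classic phases run in a loop: selection descends by
the upper confidence bound

    UCB = V_i + 2 sqrt(ln N / n_i)

(V_i the mean backpropagated complex score below node i, N the parent's visit
count, n_i the node's own), expansion creates all applicable non-overlapping
children of a leaf, simulation extends the child randomly until no chain can
be added or the complex is complete, and backpropagation pushes the simulated
score up the tree. The final answer is the most-supported path (highest visit
counts), with the best simulated terminal state retained alongside it.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .assembler import (AssemblyState, apply_action, applicable_actions,
                        initial_state)
from .network import InteractionNetwork
from .structio import Subcomponent


class SearchError(ValueError):
    pass


def ucb(value_sum: float, n_i: int, parent_N: int, exploration: float = 2.0) -> float:
    """Upper confidence bound; unvisited nodes get +inf so they are tried first."""
    if parent_N < 1:
        raise SearchError("parent must have been visited at least once")
    if n_i == 0:
        return math.inf
    return value_sum / n_i + exploration * math.sqrt(math.log(parent_N) / n_i)


class SearchNode:
    """MCTS bookkeeping: one applied action, its state, visits and value."""

    __slots__ = ("action", "state", "parent", "children", "visits", "value_sum",
                 "expanded", "terminal")

    def __init__(self, state: AssemblyState, action=None, parent=None):
        self.state = state
        self.action = action
        self.parent = parent
        self.children: list[SearchNode] = []
        self.visits = 0
        self.value_sum = 0.0
        self.expanded = False
        self.terminal = False

    @property
    def mean_value(self) -> float:
        return self.value_sum / self.visits if self.visits else 0.0

    def depth(self) -> int:
        d, n = 0, self
        while n.parent is not None:
            d, n = d + 1, n.parent
        return d


def expand(node: SearchNode, network: InteractionNetwork,
           subs: dict[str, Subcomponent]) -> list[SearchNode]:
    """Create one child per applicable, overlap-free edge application.

    A node whose state is complete, or from which every candidate placement
    is rejected, is terminal.
    """
    if node.expanded:
        return node.children
    node.expanded = True
    if not node.state.is_complete:
        for action in applicable_actions(node.state, network):
            child_state = apply_action(node.state, action, network, subs)
            if child_state is not None:
                node.children.append(SearchNode(child_state, action, node))
    if not node.children:
        node.terminal = True
    return node.children


def best_child(node: SearchNode, exploration: float = 2.0) -> SearchNode:
    """Child with maximal UCB; unvisited first, ties to the lowest action index."""
    best, best_key = None, None
    for i, c in enumerate(node.children):
        key = (ucb(c.value_sum, c.visits, max(node.visits, 1), exploration), -i)
        if best_key is None or key > best_key:
            best, best_key = c, key
    if best is None:
        raise SearchError("best_child on a childless node")
    return best


def simulate_state(state: AssemblyState, network: InteractionNetwork,
                   subs: dict[str, Subcomponent],
                   rng: np.random.Generator) -> AssemblyState:
    """Random rollout: add chains until complete or nothing more can be placed.

    Candidate moves are tried in random order; the rollout stops only when
    every remaining candidate is overlap-rejected. The input state is not
    mutated (states are immutable)."""
    current = state
    while not current.is_complete:
        actions = applicable_actions(current, network)
        if not actions:
            break
        order = rng.permutation(len(actions))
        nxt = None
        for k in order:
            nxt = apply_action(current, actions[int(k)], network, subs)
            if nxt is not None:
                break
        if nxt is None:
            break
        current = nxt
    return current


def simulate(state: AssemblyState, network: InteractionNetwork,
             subs: dict[str, Subcomponent], rng: np.random.Generator) -> float:
    """Score of a random rollout from ``state`` (complex score of the end state)."""
    return simulate_state(state, network, subs, rng).score


def backpropagate(node: SearchNode, score: float) -> None:
    """Add one visit and the (normalized) score to the node and every ancestor."""
    n = node
    while n is not None:
        n.visits += 1
        n.value_sum += score
        n = n.parent


@dataclass
class SearchConfig:
    max_iterations: int = 10_000
    seed: int = 0
    no_improve_stop: int = 500
    time_budget: float | None = None  # seconds, wall clock; None = unlimited
    exploration: float = 2.0
    normalization: Literal["running_max", "raw", "fixed"] = "running_max"
    fixed_divisor: float = 1.0
    restarts: Literal["per_seq", "single"] = "per_seq"


@dataclass
class SearchResult:
    """Outcome of a search: the returned state plus diagnostics.

    ``state`` is the better (by completeness, then score) of the
    most-supported path's terminal state and the best simulated terminal
    state; both constituents are kept for inspection."""

    state: AssemblyState
    most_supported_state: AssemblyState
    best_simulated_state: AssemblyState
    complete: bool
    iterations: int
    n_restarts: int
    seed: int
    budget_exhausted: bool = False
    log: list[dict] = field(default_factory=list)


def _state_key(state: AssemblyState) -> tuple[float, float]:
    return (state.completeness, state.score)


class _Normalizer:
    def __init__(self, mode: str, fixed_divisor: float):
        self.mode = mode
        self.fixed = fixed_divisor
        self.running_max = 0.0

    def __call__(self, raw: float) -> float:
        if self.mode == "raw":
            return raw
        if self.mode == "fixed":
            return raw / self.fixed
        self.running_max = max(self.running_max, abs(raw))
        return raw / self.running_max if self.running_max > 0 else 0.0


def _most_supported_state(root: SearchNode) -> AssemblyState:
    """Descend by visit count (ties: mean value, then order) to the supported leaf."""
    node = root
    while node.children:
        visited = [c for c in node.children if c.visits > 0]
        if not visited:
            break
        node = max(visited, key=lambda c: (c.visits, c.mean_value,
                                           -node.children.index(c)))
    return node.state


def run_search(network: InteractionNetwork, subs: dict[str, Subcomponent],
               stoichiometry: dict[str, int],
               config: SearchConfig | None = None) -> SearchResult:
    """Full MCTS over assembly paths, with deterministic per-seq restarts.

    One search tree is grown per restart root (by default one per unique
    seq_id, since a single random root can strand the search in a poorly
    connected corner of the network); the best state across restarts wins.
    Identical seed, config and inputs give bit-identical results.
    """
    if config is None:
        config = SearchConfig()
    if sum(stoichiometry.values()) < 1:
        raise SearchError("empty stoichiometry")

    seqs = sorted(stoichiometry)
    master = np.random.SeedSequence(config.seed)
    if config.restarts == "per_seq":
        roots = seqs
    else:
        pick = np.random.default_rng(master.spawn(1)[0])
        roots = [seqs[int(pick.integers(len(seqs)))]]
    children_seeds = master.spawn(len(roots))

    t0 = time.monotonic()
    best_overall: AssemblyState | None = None
    best_supported: AssemblyState | None = None
    log: list[dict] = []
    total_iters = 0
    budget_exhausted = False

    for restart, (root_seq, seed_seq) in enumerate(zip(roots, children_seeds)):
        rng = np.random.default_rng(seed_seq)
        root = SearchNode(initial_state(network, subs, root_seq))
        norm = _Normalizer(config.normalization, config.fixed_divisor)
        best_here: AssemblyState = root.state
        since_improve = 0

        for it in range(config.max_iterations):
            if config.time_budget is not None and time.monotonic() - t0 > config.time_budget:
                budget_exhausted = True
                break
            total_iters += 1
            node = root
            while node.expanded and node.children:
                node = best_child(node, config.exploration)
            if not node.expanded:
                expand(node, network, subs)
                if node.children:
                    node = best_child(node, config.exploration)
            end_state = simulate_state(node.state, network, subs, rng)
            backpropagate(node, norm(end_state.score))
            log.append({
                "restart": restart, "root_seq": root_seq, "iteration": it,
                "depth": node.depth(), "placed": node.state.n_placed,
                "rollout_score": end_state.score,
                "rollout_completeness": end_state.completeness,
            })
            if _state_key(end_state) > _state_key(best_here):
                best_here = end_state
                since_improve = 0
            else:
                since_improve += 1
            if root.terminal or since_improve >= config.no_improve_stop:
                break

        supported = _most_supported_state(root)
        if best_supported is None or _state_key(supported) > _state_key(best_supported):
            best_supported = supported
        if best_overall is None or _state_key(best_here) > _state_key(best_overall):
            best_overall = best_here
        if budget_exhausted:
            break

    assert best_overall is not None and best_supported is not None
    final = best_supported if _state_key(best_supported) >= _state_key(best_overall) \
        else best_overall
    return SearchResult(
        state=final,
        most_supported_state=best_supported,
        best_simulated_state=best_overall,
        complete=final.is_complete,
        iterations=total_iters,
        n_restarts=len(roots),
        seed=config.seed,
        budget_exhausted=budget_exhausted,
        log=log,
    )
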