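"""Synthetic ground-truth complexes and sliced subcomponents for testing.

Real inputs to the assembler are AlphaFold-family predictions of 2-3 chain
subcomponents. This module fabricates the whole chain of custody at toy
scale: an idealized chain template (a compact spherical-spiral CA trace with
CB pseudo-atoms offset outward) is copied into symmetric arrangements —
cyclic rings, dihedral double rings, linear trees, asymmetric packings —
then sliced into overlapping subcomponent files with optional coordinate
noise and synthetic plDDT. Everything is deterministic given the seed.

What this emulates: chain copies, symmetry classes, interface geometry,
copy-number bookkeeping, prediction noise, confidence patterns. What it does
not: real protein geometry, side chains, or predictor-correlated error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry, structio
from .network import detect_interaction
from .structio import ChainStructure, ResidueRecord, Subcomponent

# template geometry (A): CA trace on a sphere, CB offset radially outward
TEMPLATE_RADIUS = 6.0
CB_OFFSET = 1.5
SPIRAL_TURNS = 5.0
CENTER_SPACING = 16.5  # distance between adjacent chain centroids

AA_ALPHABET = "ACDEFHIKLMNPQRSTVWY"  # no glycine: CB is a real pseudo-atom


class GenerationError(ValueError):
    pass


@dataclass
class FixtureSpec:
    symmetry: Literal["cyclic", "dihedral", "linear_tree", "asymmetric"]
    n_chains: int
    chain_length: int = 24
    radius: float | None = None  # ring radius override, A
    noise_sigma: float = 0.0
    plddt_model: tuple = ("constant", 90.0)
    oligomer: Literal["homo", "hetero"] = "homo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 3:
            raise GenerationError("need >= 3 chains")
        if self.chain_length < 10:
            raise GenerationError("need >= 10 residues per chain")
        if self.noise_sigma < 0:
            raise GenerationError("noise_sigma must be >= 0")
        if self.symmetry == "dihedral" and self.n_chains % 2:
            raise GenerationError("dihedral fixtures need an even chain count")


@dataclass
class GroundTruth:
    """A generated complex: world-frame chains plus the true interaction graph."""

    chains: list[ChainStructure]
    adjacency: list[tuple[int, int]]  # index pairs passing detect_interaction
    sequences: dict[str, str]
    stoichiometry: dict[str, int]
    spec: FixtureSpec = field(repr=False, default=None)

    @property
    def seq_of(self) -> list[str]:
        return [c.seq_id for c in self.chains]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        structio.write_structure(self.chains, out_dir / "truth.pdb")
        structio.write_fasta(self.sequences, out_dir / "sequences.fasta")
        with open(out_dir / "stoichiometry.txt", "w") as fh:
            for sid, cnt in sorted(self.stoichiometry.items()):
                fh.write(f"{sid}:{cnt}\n")
        with open(out_dir / "adjacency.tsv", "w") as fh:
            fh.write("chain_a\tchain_b\tseq_a\tseq_b\n")
            for i, j in self.adjacency:
                fh.write(f"{self.chains[i].chain_id}\t{self.chains[j].chain_id}"
                         f"\t{self.seq_of[i]}\t{self.seq_of[j]}\n")


def template_coords(length: int) -> tuple[np.ndarray, np.ndarray]:
    """CA/CB coordinates of the idealized chain, centred at the origin.

    The CA trace is a spherical spiral (consecutive spacing ~4 A at the
    equator of a 6 A sphere); CBs sit 1.5 A radially outward, so the chain is
    a compact, roughly isotropic blob that packs like a sphere.
    """
    k = np.arange(length)
    phi = np.pi * (k + 0.5) / length
    lam = SPIRAL_TURNS * phi
    ca = TEMPLATE_RADIUS * np.stack(
        [np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi)], axis=1)
    cb = ca * (TEMPLATE_RADIUS + CB_OFFSET) / TEMPLATE_RADIUS
    return ca, cb


def _make_chain(chain_id: str, seq: str, rotation: np.ndarray,
                translation: np.ndarray, plddt: float = 90.0) -> ChainStructure:
    ca, cb = template_coords(len(seq))
    ca = ca @ rotation.T + translation
    cb = cb @ rotation.T + translation
    residues = [
        ResidueRecord(i + 1, seq[i], ca[i], cb[i], plddt) for i in range(len(seq))
    ]
    return ChainStructure(chain_id, residues)


def _rz(angle: float) -> np.ndarray:
    return Rotation.from_euler("z", angle).as_matrix()


def _placements(spec: FixtureSpec, rng: np.random.Generator
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """(rotation, translation) per chain for the requested symmetry class."""
    n, d = spec.n_chains, CENTER_SPACING
    out = []
    if spec.symmetry == "cyclic":
        R = spec.radius if spec.radius is not None else d / (2 * np.sin(np.pi / n))
        for i in range(n):
            rot = _rz(2 * np.pi * i / n)
            out.append((rot, rot @ np.array([R, 0.0, 0.0])))
    elif spec.symmetry == "dihedral":
        m = n // 2
        R = spec.radius if spec.radius is not None else d / (2 * np.sin(np.pi / m))
        chord = 2 * R * np.sin(np.pi / (2 * m))
        if chord >= d:
            raise GenerationError("ring radius too large for inter-ring contacts")
        h = np.sqrt(d * d - chord * chord) / 2
        flip = Rotation.from_euler("x", np.pi).as_matrix()
        for i in range(m):  # upper ring
            rot = _rz(2 * np.pi * i / m)
            out.append((rot, rot @ np.array([R, 0.0, h])))
        for i in range(m):  # lower ring: two-fold flip, offset half a step
            rot = _rz(2 * np.pi * i / m + np.pi / m) @ flip
            out.append((rot, _rz(2 * np.pi * i / m + np.pi / m)
                        @ np.array([R, 0.0, 0.0]) + np.array([0.0, 0.0, -h])))
    elif spec.symmetry == "linear_tree":
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(n):
            out.append((_rz(golden * i), np.array([d * i, 0.0, 0.0])))
    elif spec.symmetry == "asymmetric":
        centers = [np.zeros(3)]
        for _ in range(n - 1):
            for _attempt in range(2000):
                base = centers[int(rng.integers(len(centers)))]
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = base + d * u
                dists = [np.linalg.norm(cand - c) for c in centers]
                if min(dists) >= d - 0.3:
                    centers.append(cand)
                    break
            else:
                raise GenerationError("could not pack chains without overlap")
        for c in centers:
            out.append((Rotation.random(rng=rng).as_matrix(), c))
    else:
        raise GenerationError(f"unknown symmetry {spec.symmetry!r}")
    return out


def generate_complex(spec: FixtureSpec) -> GroundTruth:
    """Build the ground-truth complex and its true interaction adjacency.

    The generated truth is validated: the contact graph must be connected and
    free of overlap-predicate violations and clashes, otherwise the spec is
    rejected (typically the ring radius is too small).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_chains
    if spec.oligomer == "homo":
        seq_ids = ["S0"] * n
        sequences = {"S0": _random_sequence(spec.chain_length, rng)}
    else:
        seq_ids = [f"S{i}" for i in range(n)]
        sequences = {}
        while len(sequences) < n:  # distinct sequences per position
            s = _random_sequence(spec.chain_length, rng)
            if s not in sequences.values():
                sequences[f"S{len(sequences)}"] = s

    chains = []
    for i, (rot, trans) in enumerate(_placements(spec, rng)):
        cid = structio.PDB_CHAIN_IDS[i]
        chain = _make_chain(cid, sequences[seq_ids[i]], rot, trans)
        chain.seq_id = seq_ids[i]
        chains.append(chain)

    adjacency = [
        (i, j) for i, j in combinations(range(n), 2)
        if detect_interaction(chains[i], chains[j])
    ]
    _validate_truth(chains, adjacency)

    stoich: dict[str, int] = {}
    for sid in seq_ids:
        stoich[sid] = stoich.get(sid, 0) + 1
    return GroundTruth(chains, adjacency, sequences, stoich, spec)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[int(k)] for k in rng.integers(len(AA_ALPHABET), size=length))


def _validate_truth(chains: list[ChainStructure], adjacency: list[tuple[int, int]]) -> None:
    n = len(chains)
    for i, j in combinations(range(n), 2):
        if geometry.is_overlap(chains[i], chains[j]):
            raise GenerationError(f"truth chains {i},{j} violate the overlap predicate")
        if geometry.count_clashes(chains[i], chains[j]):
            raise GenerationError(f"truth chains {i},{j} clash")
    # connectivity of the contact graph
    seen = {0}
    frontier = [0]
    neigh: dict[int, list[int]] = {k: [] for k in range(n)}
    for i, j in adjacency:
        neigh[i].append(j)
        neigh[j].append(i)
    while frontier:
        nxt = frontier.pop()
        for k in neigh[nxt]:
            if k not in seen:
                seen.add(k)
                frontier.append(k)
    if len(seen) != n:
        raise GenerationError("truth contact graph is not connected")


# --- slicing into subcomponents ---------------------------------------------

SliceMode = Literal["native_dimers", "native_trimers", "all_trimers"]


def slice_subcomponents(truth: GroundTruth, mode: SliceMode = "native_trimers",
                        noise_sigma: float | None = None,
                        plddt_model: tuple | None = None,
                        seed: int | None = None,
                        out_dir: str | Path | None = None) -> list[Subcomponent]:
    """Cut the truth into subcomponents the way a predictor would be asked to.

    native modes keep adjacent pairs / connected triples; all_trimers keeps
    every 3-subset regardless of contact. Groups are deduplicated by their
    sorted seq-id tuple (predictions are made per unique sequence combination,
    so a homomer yields a single unique file per size). Each subcomponent is
    re-centred in its own frame, optionally perturbed with isotropic Gaussian
    coordinate noise, and given synthetic plDDT B-factors.
    """
    spec = truth.spec
    noise = spec.noise_sigma if (noise_sigma is None and spec) else (noise_sigma or 0.0)
    model = plddt_model if plddt_model is not None else (
        spec.plddt_model if spec else ("constant", 90.0))
    rng = np.random.default_rng(np.random.SeedSequence(
        spec.seed + 1 if (seed is None and spec) else (seed or 0)))

    adj = set(map(frozenset, truth.adjacency))
    n = len(truth.chains)
    if mode == "native_dimers":
        groups = [tuple(sorted(p)) for p in sorted(map(tuple, map(sorted, adj)))]
    elif mode == "native_trimers":
        groups = [t for t in combinations(range(n), 3) if _connected_triple(t, adj)]
    elif mode == "all_trimers":
        groups = list(combinations(range(n), 3))
    else:
        raise GenerationError(f"unknown slice mode {mode!r}")

    seen_keys = set()
    subs: list[Subcomponent] = []
    seq_of = truth.seq_of
    for grp in groups:
        key = tuple(sorted(seq_of[i] for i in grp))
        if key in seen_keys:
            continue
        seen_keys.add(key)
        members = [truth.chains[i] for i in grp]
        centroid = np.vstack([c.ca_coords for c in members]).mean(axis=0)
        local = []
        for k, c in enumerate(members):
            cid = "ABC"[k]
            residues = []
            for r in c.residues:
                ca = r.ca - centroid
                cb = r.cb - centroid
                if noise > 0:
                    ca = ca + rng.normal(scale=noise, size=3)
                    cb = cb + rng.normal(scale=noise, size=3)
                residues.append(ResidueRecord(r.index, r.aa, ca, cb, r.plddt))
            local.append(ChainStructure(cid, residues, seq_id=c.seq_id))
        _apply_plddt(local, model)
        name = ("dimer_" if len(grp) == 2 else "trimer_") + \
            "".join(truth.chains[i].chain_id for i in grp)
        subs.append(Subcomponent(name, local, {c.chain_id: c.seq_id for c in local}))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sub in subs:
            structio.write_structure(sub.chains, out_dir / f"{sub.name}.pdb")
    return subs


def _connected_triple(t: tuple[int, int, int], adj: set[frozenset]) -> bool:
    present = sum(frozenset(p) in adj for p in combinations(t, 2))
    return present >= 2  # a path or a triangle among the three chains


def _apply_plddt(chains: list[ChainStructure], model: tuple) -> None:
    """Fill plDDT per the model: ('constant', v) or ('decay', hi, lo, scale).

    The decay model gives high confidence at residues near another chain in
    the local frame and decaying confidence away from the interface."""
    kind = model[0]
    if kind == "constant":
        value = float(model[1])
        for c in chains:
            c.residues = [ResidueRecord(r.index, r.aa, r.ca, r.cb, value)
                          for r in c.residues]
            c._cache.clear()
    elif kind == "decay":
        hi, lo, scale = (float(v) for v in model[1:4])
        for c in chains:
            others = np.vstack([o.ca_coords for o in chains if o is not c])
            d = np.linalg.norm(c.ca_coords[:, None, :] - others[None, :, :],
                               axis=2).min(axis=1)
            vals = np.clip(lo + (hi - lo) * np.exp(-np.maximum(d - 8.0, 0) / scale),
                           0.0, 100.0)
            c.residues = [ResidueRecord(r.index, r.aa, r.ca, r.cb, float(v))
                          for r, v in zip(c.residues, vals)]
            c._cache.clear()
    else:
        raise GenerationError(f"unknown plDDT model {model!r}")


# --- corruption operators ---------------------------------------------------

def corrupt(subs: list[Subcomponent], ops: list[tuple], seed: int = 0
            ) -> list[Subcomponent]:
    """Apply failure-mode operators to a subcomponent list (copies; input untouched).

    Supported ops: ("drop_edge", (seq_a, seq_b)) removes every subcomponent
    realizing that interacting pair; ("clash_inject",) slides one chain of one
    subcomponent so at least one atom pair falls below 1 A; and
    ("wrong_conformation",) rolls one chain about its interface axis so the
    interface geometry changes while the interaction itself survives.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = [Subcomponent(s.name, [c.renamed(c.chain_id) for c in s.chains],
                        dict(s.seq_assignment)) for s in subs]
    for op in ops:
        kind = op[0]
        if kind == "drop_edge":
            pair = frozenset(op[1])
            keep = []
            dropped = 0
            for s in out:
                realizes = any(
                    frozenset((a.seq_id, b.seq_id)) == pair and detect_interaction(a, b)
                    for a, b in combinations(s.chains, 2))
                if realizes:
                    dropped += 1
                else:
                    keep.append(s)
            if not dropped:
                raise GenerationError(f"no subcomponent realizes edge {sorted(pair)}")
            out = keep
        elif kind == "clash_inject":
            s = out[int(rng.integers(len(out)))]
            a, b = s.chains[0], s.chains[1]
            pa, pb = a.atom_coords, b.atom_coords
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            gap = pa[i] - pb[j]
            shift = gap * (1 - 0.5 / max(np.linalg.norm(gap), 1e-9))
            s.chains[1] = b.transformed(np.eye(3), shift)
            s.chains[1].seq_id = b.seq_id
        elif kind == "wrong_conformation":
            s = out[int(rng.integers(len(out)))]
            a, b = s.chains[0], s.chains[1]
            axis = b.ca_coords.mean(0) - a.ca_coords.mean(0)
            axis /= max(np.linalg.norm(axis), 1e-9)
            rot = Rotation.from_rotvec(np.pi / 3 * axis).as_matrix()
            center = b.ca_coords.mean(0)
            s.chains[1] = b.transformed(rot, center - rot @ center)
            s.chains[1].seq_id = b.seq_id
            if not detect_interaction(s.chains[0], s.chains[1]):
                raise GenerationError("wrong_conformation broke the interaction")
        else:
            raise GenerationError(f"unknown corruption op {kind!r}")
    return out
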