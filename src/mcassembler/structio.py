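"""Structure I/O: multi-chain PDB reading/writing with per-residue confidence.

The data model is deliberately reduced: each residue carries its CA and CB
coordinates (CB falling back to CA for glycine, the AlphaFold interface
convention) and a per-residue plDDT read from the B-factor column of the CA
atom, which is where AlphaFold-family predictors store it.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: chain identifiers legal in single-character PDB chain ID fields
PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


class StructureError(ValueError):
    """Raised for unreadable, empty or contract-violating structures."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: sequential number, one-letter code, CA/CB positions, plDDT."""

    index: int
    aa: str
    ca: np.ndarray
    cb: np.ndarray
    plddt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        object.__setattr__(self, "cb", np.asarray(self.cb, dtype=float))
        if not (np.all(np.isfinite(self.ca)) and np.all(np.isfinite(self.cb))):
            raise StructureError(f"non-finite coordinates in residue {self.index}")
        if not 0.0 <= self.plddt <= 100.0:
            raise StructureError(f"plDDT {self.plddt} outside [0, 100] in residue {self.index}")

    @classmethod
    def _unchecked(cls, index: int, aa: str, ca: np.ndarray, cb: np.ndarray,
                   plddt: float) -> "ResidueRecord":
        """Construction without re-validation, for records derived from valid ones."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "index", index)
        object.__setattr__(obj, "aa", aa)
        object.__setattr__(obj, "ca", ca)
        object.__setattr__(obj, "cb", cb)
        object.__setattr__(obj, "plddt", plddt)
        return obj


@dataclass
class ChainStructure:
    """A single polypeptide chain with CA/CB coordinates and plDDT.

    ``seq_id`` labels the unique-sequence identity of the chain (several chain
    copies of a homomer share one seq_id); it is None until assigned.
    """

    chain_id: str
    residues: list[ResidueRecord]
    seq_id: str | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise StructureError(f"chain {self.chain_id} has no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(f"chain {self.chain_id}: residue indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        if "ca" not in self._cache:
            self._cache["ca"] = np.array([r.ca for r in self.residues])
        return self._cache["ca"]

    @property
    def cb_coords(self) -> np.ndarray:
        if "cb" not in self._cache:
            self._cache["cb"] = np.array([r.cb for r in self.residues])
        return self._cache["cb"]

    @property
    def atom_coords(self) -> np.ndarray:
        """All stored atom positions (CA then CB rows)."""
        return np.vstack([self.ca_coords, self.cb_coords])

    @property
    def plddts(self) -> np.ndarray:
        if "plddt" not in self._cache:
            self._cache["plddt"] = np.array([r.plddt for r in self.residues])
        return self._cache["plddt"]

    @property
    def plddt_by_index(self) -> dict[int, float]:
        if "plddt_by_index" not in self._cache:
            self._cache["plddt_by_index"] = {r.index: r.plddt for r in self.residues}
        return self._cache["plddt_by_index"]

    @property
    def residue_indices(self) -> np.ndarray:
        if "idx" not in self._cache:
            self._cache["idx"] = np.array([r.index for r in self.residues])
        return self._cache["idx"]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation)
        t = np.asarray(translation)
        ca = self.ca_coords @ R.T + t
        cb = self.cb_coords @ R.T + t
        new = [
            ResidueRecord._unchecked(r.index, r.aa, ca[i], cb[i], r.plddt)
            for i, r in enumerate(self.residues)
        ]
        out = ChainStructure(self.chain_id, new, seq_id=self.seq_id)
        out._cache["ca"] = ca
        out._cache["cb"] = cb
        return out

    def renamed(self, chain_id: str) -> "ChainStructure":
        return ChainStructure(chain_id, self.residues, seq_id=self.seq_id)


@dataclass
class Subcomponent:
    """A predicted 2-3 chain building block in its own local frame."""

    name: str
    chains: list[ChainStructure]
    seq_assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not 2 <= len(self.chains) <= 3:
            raise StructureError(f"subcomponent {self.name}: needs 2-3 chains, has {len(self.chains)}")
        for c in self.chains:
            if c.chain_id not in self.seq_assignment:
                raise StructureError(f"subcomponent {self.name}: chain {c.chain_id} has no seq_id")
            c.seq_id = self.seq_assignment[c.chain_id]

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def read_structure(path: str | Path) -> list[ChainStructure]:
    """Read a PDB file into one ChainStructure per chain.

    plDDT is taken from the B-factor of the CA atom; residues without a CA are
    dropped with a warning; CB falls back to CA when absent (glycine).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    chains: list[ChainStructure] = []
    for chain in st[0]:
        residues = []
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is None:
                logger.warning("%s: chain %s residue %s %d lacks CA, dropped",
                               path.name, chain.name, res.name, res.seqid.num)
                continue
            cb = res.find_atom("CB", "*")
            ca_pos = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
            cb_pos = ca_pos if cb is None else np.array([cb.pos.x, cb.pos.y, cb.pos.z])
            info = gemmi.find_tabulated_residue(res.name)
            aa = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
            plddt = float(min(max(ca.b_iso, 0.0), 100.0))
            residues.append(ResidueRecord(res.seqid.num, aa, ca_pos, cb_pos, plddt))
        if residues:
            chains.append(ChainStructure(chain.name, residues))
    if not chains:
        raise StructureError(f"{path}: no chains with CA atoms")
    return chains


def write_structure(chains: list[ChainStructure], path: str | Path) -> None:
    """Write chains as a PDB file; B-factors carry plDDT, TER between chains."""
    if not chains:
        raise StructureError("refusing to write an empty chain list")
    if len(chains) > len(PDB_CHAIN_IDS):
        raise StructureError(
            f"{len(chains)} chains exceed the {len(PDB_CHAIN_IDS)} single-character PDB chain "
            "identifiers; write in batches or rename via a sidecar table"
        )
    ids = [c.chain_id for c in chains]
    if len(set(ids)) != len(ids) or any(i not in PDB_CHAIN_IDS for i in ids):
        ids = list(PDB_CHAIN_IDS[: len(chains)])

    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model("1")
    serial = 1
    for cid, chain in zip(ids, chains):
        gchain = gemmi.Chain(cid)
        for r in chain.residues:
            gres = gemmi.Residue()
            gres.name = gemmi.expand_one_letter(r.aa, gemmi.ResidueKind.AA) or "UNK"
            gres.seqid = gemmi.SeqId(r.index, " ")
            for name, elem, pos in (("CA", "C", r.ca), ("CB", "C", r.cb)):
                if name == "CB" and r.aa == "G":
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(*pos)
                atom.b_iso = float(r.plddt)
                atom.occ = 1.0
                atom.serial = serial
                serial += 1
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as {record id: sequence}."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise StructureError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def assign_sequences(chains: list[ChainStructure], sequences: dict[str, str]) -> dict[str, str]:
    """Map each chain to the unique-sequence record it matches.

    An exact full-sequence match beats a substring match (the chain may lack
    unresolved residues present in the reference sequence); remaining ties are
    an error rather than a guess, since a misassigned chain corrupts the
    stoichiometry bookkeeping downstream.
    """
    out: dict[str, str] = {}
    for chain in chains:
        cseq = chain.sequence
        exact = [sid for sid, s in sequences.items() if s == cseq]
        if len(exact) == 1:
            out[chain.chain_id] = exact[0]
            continue
        if len(exact) > 1:
            raise StructureError(
                f"chain {chain.chain_id}: sequence matches records {sorted(exact)} exactly; "
                "ambiguous assignment"
            )
        sub = [sid for sid, s in sequences.items() if cseq in s]
        if len(sub) == 1:
            out[chain.chain_id] = sub[0]
        elif not sub:
            raise StructureError(f"chain {chain.chain_id}: sequence matches no FASTA record")
        else:
            raise StructureError(
                f"chain {chain.chain_id}: sequence is a substring of records {sorted(sub)}; "
                "ambiguous assignment"
            )
    return out


def parse_stoichiometry(spec: str | Path | dict[str, int]) -> dict[str, int]:
    """Parse a stoichiometry given as a dict, "seqid:count,..." string, or file."""
    if isinstance(spec, dict):
        stoich = dict(spec)
    else:
        text = None
        p = Path(str(spec))
        if p.exists():
            text = p.read_text()
        else:
            text = str(spec)
        stoich = {}
        for tok in text.replace(",", "\n").split():
            if not tok.strip():
                continue
            sid, _, cnt = tok.partition(":")
            stoich[sid.strip()] = int(cnt)
    for sid, cnt in stoich.items():
        if cnt < 1:
            raise StructureError(f"stoichiometry of {sid} must be >= 1, got {cnt}")
    return stoich
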