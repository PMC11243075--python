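"""Molecular graphs for graph machines: tagged-SMILES parsing and rooted DAGs.

A graph machine estimates a property of a single atom — here the chemical
shift of one benzenic carbon — by composing a shared node function over a
directed acyclic graph whose shape mirrors the molecule's 2D structure.  The
carbon of interest is marked with a SMILES atom-map tag (``[c:1]``) and
becomes the root of the DAG; every other heavy atom feeds, directly or
through intermediates, into the root.

Hydrogens are implicit: graphs contain heavy atoms only, and hydrogen enters
the model through the valence input of the node function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

#: Heavy elements allowed in a molecule (hydrogen is implicit).
SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "O", "N", "S", "P", "Si", "F", "Cl", "Br", "I")

_ELEMENT_INDEX = {sym: i for i, sym in enumerate(SUPPORTED_ELEMENTS)}


class SmilesParseError(ValueError):
    """Raised for SMILES that RDKit cannot parse or sanitize."""


class TagCountError(ValueError):
    """Raised when a tagged SMILES has zero or more than one atom-map tag."""


class UnsupportedElementError(ValueError):
    """Raised when a molecule contains an element outside the supported set."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unsupported element: {symbol!r} "
                         f"(supported heavy atoms: {', '.join(SUPPORTED_ELEMENTS)})")


class ApplicabilityWarning(UserWarning):
    """Emitted when a prediction request falls outside the model's scope."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, aromaticity, implicit Hs and valence.

    ``valence`` is the sum of bond orders including implicit hydrogens, with
    aromatic bonds counted as 1.5 and the total rounded to the nearest
    integer — an aromatic ring carbon therefore has valence 4 whether or not
    it bears a substituent.
    """

    index: int
    symbol: str
    aromatic: bool
    n_hydrogens: int
    heavy_degree: int
    valence: int


@dataclass(frozen=True)
class TaggedMolecule:
    """Heavy-atom molecular graph with one tagged carbon of interest."""

    source_text: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, float], ...]
    tagged_index: int
    rdkit_mol: Chem.Mol = field(repr=False, compare=False, hash=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def canonical_tagged_smiles(self) -> str:
        """Canonical SMILES carrying the atom-map tag on the root carbon."""
        return Chem.MolToSmiles(self.rdkit_mol)

    def neighbors(self, idx: int) -> list[int]:
        out: list[int] = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    def symmetry_ranks(self) -> tuple[int, ...]:
        """Canonical symmetry classes, computed with the tag stripped."""
        bare = Chem.Mol(self.rdkit_mol)
        for atom in bare.GetAtoms():
            atom.SetAtomMapNum(0)
        return tuple(Chem.CanonicalRankAtoms(bare, breakTies=False))


@dataclass(frozen=True)
class RootedDAG:
    """Directed acyclic graph of heavy atoms oriented toward the tagged root.

    Edges point child -> parent; the root (the carbon of interest) is the
    unique sink.  ``topo_order`` lists node ids leaves-first, root-last, so a
    single pass in that order evaluates every node after its children.  A node
    reachable by two paths (ring closure) is a single shared node whose output
    fans out to all of its parents.
    """

    molecule: TaggedMolecule
    root: int
    levels: tuple[int, ...]
    children: tuple[tuple[int, ...], ...]
    parents: tuple[tuple[int, ...], ...]
    topo_order: tuple[int, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.levels)

    @property
    def n_edges(self) -> int:
        return sum(len(c) for c in self.children)

    def structure_signature(self) -> tuple:
        """Rooted-isomorphism invariant: canonical nested tuple of the DAG.

        Two DAGs have equal signatures iff they are isomorphic as rooted DAGs
        with matching atom types and valences (shared nodes are expanded, which
        is harmless at these sizes).
        """
        atoms = self.molecule.atoms

        def key(node: int) -> tuple:
            a = atoms[node]
            return (a.symbol, a.valence, tuple(sorted(key(c) for c in self.children[node])))

        return key(self.root)


def _validate_elements(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _ELEMENT_INDEX:
            raise UnsupportedElementError(atom.GetSymbol())


def _atom_records(mol: Chem.Mol) -> tuple[AtomRecord, ...]:
    records = []
    for atom in mol.GetAtoms():
        order = 0.0
        for bond in atom.GetBonds():
            order += bond.GetBondTypeAsDouble()  # aromatic counts 1.5
        valence = int(round(order)) + atom.GetTotalNumHs()
        records.append(
            AtomRecord(
                index=atom.GetIdx(),
                symbol=atom.GetSymbol(),
                aromatic=atom.GetIsAromatic(),
                n_hydrogens=atom.GetTotalNumHs(),
                heavy_degree=atom.GetDegree(),
                valence=valence,
            )
        )
    return tuple(records)


def _from_rdkit(mol: Chem.Mol, source_text: str, tagged_index: int) -> TaggedMolecule:
    _validate_elements(mol)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SmilesParseError(f"disconnected structure: {source_text!r}")
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble()) for b in mol.GetBonds()
    )
    return TaggedMolecule(
        source_text=source_text,
        atoms=_atom_records(mol),
        bonds=bonds,
        tagged_index=tagged_index,
        rdkit_mol=mol,
    )


def parse_tagged_smiles(text: str) -> TaggedMolecule:
    """Parse an atom-tagged SMILES such as ``COc1[c:1](C)cccc1``.

    Exactly one atom must carry an atom-map number, and it must be a carbon;
    it becomes the carbon of interest (the DAG root).  Kekulé input is
    normalized to aromatic perception by RDKit sanitization.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {text!r}")
    tagged = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]
    if len(tagged) != 1:
        raise TagCountError(
            f"expected exactly one atom-map tag, found {len(tagged)} in {text!r}"
        )
    idx = tagged[0]
    if mol.GetAtomWithIdx(idx).GetSymbol() != "C":
        raise TagCountError(f"tagged atom must be carbon, got "
                            f"{mol.GetAtomWithIdx(idx).GetSymbol()} in {text!r}")
    return _from_rdkit(mol, text, idx)


def _benzenic_ring_atoms(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Six-membered, all-carbon, aromatic, non-fused rings."""
    info = mol.GetRingInfo()
    rings = [tuple(r) for r in info.AtomRings()]
    out = []
    for ring in rings:
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetSymbol() == "C" and a.GetIsAromatic() for a in atoms):
            continue
        if any(info.NumAtomRings(i) > 1 for i in ring):
            continue  # fused
        out.append(ring)
    return out


def enumerate_ring_carbons(text: str) -> list[TaggedMolecule]:
    """One TaggedMolecule per carbon of each isolated benzenic ring.

    Returns the variants in atom-index order.  A molecule with no isolated
    benzenic ring yields an empty list and an :class:`ApplicabilityWarning`.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {text!r}")
    ring_atoms = sorted({i for ring in _benzenic_ring_atoms(mol) for i in ring})
    if not ring_atoms:
        warnings.warn(
            f"no isolated benzenic ring in {text!r}; nothing to predict",
            ApplicabilityWarning,
            stacklevel=2,
        )
        return []
    out = []
    for idx in ring_atoms:
        tagged = Chem.Mol(mol)
        for atom in tagged.GetAtoms():
            atom.SetAtomMapNum(0)
        tagged.GetAtomWithIdx(idx).SetAtomMapNum(1)
        out.append(_from_rdkit(tagged, Chem.MolToSmiles(tagged), idx))
    return out


def build_rooted_dag(mol: TaggedMolecule) -> RootedDAG:
    """Orient the molecular graph toward the tagged carbon.

    Levels are breadth-first distances from the root; each bond becomes an
    edge from the deeper atom to the shallower one.  A bond between two atoms
    of the same level (only possible in odd rings) is oriented from higher
    canonical symmetry rank to lower, ties broken by atom index, which keeps
    the graph acyclic because each node has at most one same-level outgoing
    edge.  Children of each node are ordered by (canonical rank, atom index)
    so that the DAG — and every downstream prediction — is invariant under
    SMILES rewriting.
    """
    n = mol.n_atoms
    root = mol.tagged_index
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)

    levels = [-1] * n
    levels[root] = 0
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if levels[v] < 0:
                    levels[v] = levels[u] + 1
                    nxt.append(v)
        frontier = nxt

    ranks = mol.symmetry_ranks()
    children: list[list[int]] = [[] for _ in range(n)]
    parents: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in mol.bonds:
        if levels[i] == levels[j]:
            # odd-ring tie edge: higher rank feeds lower rank
            child, parent = ((i, j) if (ranks[i], i) > (ranks[j], j) else (j, i))
        elif levels[i] > levels[j]:
            child, parent = i, j
        else:
            child, parent = j, i
        children[parent].append(child)
        parents[child].append(parent)

    for node in range(n):
        children[node].sort(key=lambda c: (ranks[c], c))

    # leaves first: deeper levels first, within a level higher rank first so
    # that same-level tie edges are respected
    topo = sorted(range(n), key=lambda u: (-levels[u], -ranks[u], -u))
    pos = {u: k for k, u in enumerate(topo)}
    for parent in range(n):
        for child in children[parent]:
            if pos[child] >= pos[parent]:  # pragma: no cover - structural guard
                raise AssertionError("topological order violated")

    return RootedDAG(
        molecule=mol,
        root=root,
        levels=tuple(levels),
        children=tuple(tuple(c) for c in children),
        parents=tuple(tuple(p) for p in parents),
        topo_order=tuple(topo),
    )


@dataclass(frozen=True)
class ApplicabilityReport:
    """Warnings about a molecule relative to the model's training domain.

    Warnings never block prediction; the model computes a shift for any
    parseable structure, but structures unlike the training molecules
    (fused aromatics, heteroaromatics, unseen elements) are unreliable.
    """

    warnings: tuple[str, ...]

    def __bool__(self) -> bool:
        return bool(self.warnings)


def check_applicability(
    mol: TaggedMolecule, training_elements: set[str] | None = None
) -> ApplicabilityReport:
    """Flag features of ``mol`` that fall outside the usual training domain."""
    notes: list[str] = []
    if training_elements is not None:
        unseen = sorted({a.symbol for a in mol.atoms} - set(training_elements))
        if unseen:
            notes.append(f"elements not in training profile: {', '.join(unseen)}")

    rd = mol.rdkit_mol
    info = rd.GetRingInfo()
    idx = mol.tagged_index
    atom = rd.GetAtomWithIdx(idx)
    in_benzenic = any(idx in ring for ring in _benzenic_ring_atoms(rd))
    if not in_benzenic:
        if info.NumAtomRings(idx) > 1 or any(
            info.NumAtomRings(i) > 1 and rd.GetAtomWithIdx(i).GetIsAromatic()
            for ring in info.AtomRings()
            if idx in ring
            for i in ring
        ):
            notes.append("fused aromatic bicycle")
        elif atom.GetIsAromatic():
            notes.append("heteroaromatic ring")
        else:
            notes.append("tagged carbon is not on an isolated benzenic ring")
    return ApplicabilityReport(warnings=tuple(notes))
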