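"""Synthetic benzenic shift datasets with known ground truth.

Two generators produce desk-scale stand-ins for experimental shift tables,
so every stage of the pipeline is testable end to end:

* an *additive* oracle in the style of classical substituent-increment
  tables: the shift of a ring carbon is the unsubstituted-benzene value
  plus one increment per substituent, chosen by the substituent's position
  (ipso/ortho/meta/para) relative to that carbon;
* a *teacher* graph machine with fixed random parameters, whose outputs a
  trained student should recover up to the injected noise.

The increment values shipped in the default library are engineering
constants in the style of standard tables; tests rely only on their
internal consistency, not on any particular ppm value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_graph import TaggedMolecule, build_rooted_dag, enumerate_ring_carbons
from .node_model import NodeFunctionParameters, PackedGraphs, ScalingSpec
from .training import ShiftDataset

#: shift of an unsubstituted benzene carbon, ppm
BASE_SHIFT = 128.5

#: (ipso, ortho, meta, para) increments in ppm, keyed by substituent SMILES
#: written with a leading ``*`` dummy atom at the attachment point
DEFAULT_INCREMENTS: dict[str, tuple[float, float, float, float]] = {
    "*C": (9.3, 0.7, -0.1, -2.9),            # methyl
    "*OC": (31.4, -14.4, 1.0, -7.7),         # methoxy
    "*O": (26.9, -12.7, 1.4, -7.3),          # hydroxy
    "*N": (18.0, -13.3, 0.9, -9.8),          # amino
    "*[N+](=O)[O-]": (20.0, -4.8, 0.9, 5.8),  # nitro
    "*F": (34.8, -12.9, 1.4, -4.5),
    "*Cl": (6.2, 0.4, 1.3, -1.9),
    "*Br": (-5.5, 3.4, 1.7, -1.6),
    "*I": (-34.1, 8.9, 1.1, -1.1),
    "*C#N": (-16.0, 3.6, 0.6, 4.3),          # cyano
    "*C=O": (8.2, 1.2, 0.5, 5.8),            # formyl
    "*C(C)=O": (8.9, 0.1, 0.0, 4.4),         # acetyl
    "*C(=O)OC": (2.0, 1.2, -0.1, 4.3),       # methyl ester
    "*C(C)(C)C": (22.1, -3.4, -0.4, -2.9),   # tert-butyl
    "*SC": (9.9, -2.0, 0.1, -3.7),           # methylthio
}


class LibraryError(KeyError):
    """A ring substituent is not present in the increment library."""


def _canonical_fragment(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid fragment SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SubstituentLibrary:
    """Monovalent substituents with positional shift increments.

    Entries are keyed by the substituent SMILES written with a leading
    ``*`` dummy atom at the attachment point; lookups canonicalize, so any
    equivalent writing of a fragment matches.
    """

    base_shift: float
    entries: dict[str, tuple[float, float, float, float]]

    def __post_init__(self):
        canonical = {}
        for key, inc in self.entries.items():
            if not key.startswith("*"):
                raise ValueError(f"fragment {key!r} must start with the * dummy atom")
            if len(inc) != 4:
                raise ValueError(f"fragment {key!r} needs (ipso, ortho, meta, para)")
            canonical[_canonical_fragment(key)] = tuple(float(v) for v in inc)
        object.__setattr__(self, "_canonical", canonical)

    @classmethod
    def default(cls) -> "SubstituentLibrary":
        return cls(base_shift=BASE_SHIFT, entries=dict(DEFAULT_INCREMENTS))

    @classmethod
    def restricted(cls, fragments) -> "SubstituentLibrary":
        """Default library cut down to the named ``*``-prefixed fragments."""
        return cls(
            base_shift=BASE_SHIFT,
            entries={k: DEFAULT_INCREMENTS[k] for k in fragments},
        )

    def lookup(self, fragment_smiles: str) -> tuple[float, float, float, float]:
        key = _canonical_fragment(fragment_smiles)
        if key not in self._canonical:
            raise LibraryError(f"substituent {fragment_smiles!r} not in library")
        return self._canonical[key]

    def branch_smiles(self) -> list[str]:
        """Substituents as SMILES branch bodies (dummy atom stripped)."""
        return [smi[1:] for smi in self.entries]


def generate_molecules(
    n: int, max_substituents: int, seed, library: SubstituentLibrary | None = None
) -> list[str]:
    """``n`` unique randomly substituted benzenes as canonical SMILES.

    Substituent count is uniform on 0..max_substituents; positions and
    groups are drawn uniformly.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= max_substituents <= 6:
        raise ValueError("max_substituents must be in 0..6")
    library = library or SubstituentLibrary.default()
    branches = library.branch_smiles()
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    stall = 0
    while len(out) < n:
        k = int(rng.integers(0, max_substituents + 1))
        positions = rng.choice(6, size=k, replace=False)
        groups = {int(p): branches[int(g)] for p, g in
                  zip(positions, rng.integers(0, len(branches), size=k))}
        parts = []
        for pos in range(6):
            atom = "c1" if pos == 0 else "c"
            if pos in groups:
                atom += f"({groups[pos]})"
            parts.append(atom)
        smi = "".join(parts) + "1"
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if canonical in seen:
            stall += 1
            if stall > 2000:
                raise ValueError(
                    f"cannot generate {n} unique molecules with "
                    f"max_substituents={max_substituents}"
                )
            continue
        stall = 0
        seen.add(canonical)
        out.append(canonical)
    return out


def _ring_substituents(mol: TaggedMolecule) -> list[tuple[int, str]]:
    """(ring distance from tagged carbon, fragment SMILES) per substituent.

    The fragment is emitted with a dummy atom at the attachment point and
    canonicalized, which is how the library keys are stored.
    """
    rd = mol.rdkit_mol
    info = rd.GetRingInfo()
    ring = None
    for r in info.AtomRings():
        if mol.tagged_index in r and len(r) == 6:
            atoms = [rd.GetAtomWithIdx(i) for i in r]
            if all(a.GetSymbol() == "C" and a.GetIsAromatic() for a in atoms):
                ring = list(r)
                break
    if ring is None:
        raise ValueError("tagged carbon is not on a benzene ring")

    # ring distance (0..3) of each ring atom from the tagged carbon
    pos_in_ring = ring.index(mol.tagged_index)
    distance = {}
    for off, atom_idx in enumerate(ring):
        d = abs(off - pos_in_ring)
        distance[atom_idx] = min(d, 6 - d)

    ring_set = set(ring)
    out = []
    for atom_idx in ring:
        for nb in rd.GetAtomWithIdx(atom_idx).GetNeighbors():
            if nb.GetIdx() in ring_set:
                continue
            # collect the substituent subgraph by flood fill off the ring
            keep = {nb.GetIdx()}
            frontier = [nb.GetIdx()]
            while frontier:
                cur = frontier.pop()
                for nxt in rd.GetAtomWithIdx(cur).GetNeighbors():
                    i = nxt.GetIdx()
                    if i not in keep and i not in ring_set:
                        keep.add(i)
                        frontier.append(i)
            frag = Chem.RWMol()
            mapping = {}
            for i in sorted(keep):
                a = rd.GetAtomWithIdx(i)
                na = Chem.Atom(a.GetSymbol())
                na.SetFormalCharge(a.GetFormalCharge())
                mapping[i] = frag.AddAtom(na)
            dummy = frag.AddAtom(Chem.Atom(0))
            frag.AddBond(dummy, mapping[nb.GetIdx()], Chem.BondType.SINGLE)
            for b in rd.GetBonds():
                i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
                if i in keep and j in keep:
                    order = b.GetBondType()
                    if order == Chem.BondType.AROMATIC:
                        order = Chem.BondType.SINGLE
                    frag.AddBond(mapping[i], mapping[j], order)
            frag_smiles = Chem.MolToSmiles(frag.GetMol())
            out.append((distance[atom_idx], frag_smiles))
    return out


def additive_shift_oracle(
    mol: TaggedMolecule, library: SubstituentLibrary | None = None
) -> float:
    """Ground-truth shift by substituent-increment additivity, in ppm."""
    library = library or SubstituentLibrary.default()
    value = library.base_shift
    for distance, frag in _ring_substituents(mol):
        inc = library.lookup(frag)
        value += inc[distance]
    return value


def teacher_parameters(h: int, seed, state_dim: int = 1) -> NodeFunctionParameters:
    """A fixed random node function to serve as data-generating teacher."""
    rng = np.random.default_rng(seed)
    return NodeFunctionParameters.random(h, rng, init_scale=0.8, state_dim=state_dim)


@dataclass(frozen=True)
class TeacherModel:
    """A data-generating graph machine with a fixed ppm calibration.

    The affine map from raw network output to ppm is calibrated once, on an
    internal probe set drawn from the teacher's own seed, so that every
    dataset generated from the same teacher shares one ground truth.
    """

    params: NodeFunctionParameters
    scaling: ScalingSpec

    def predict(self, tagged: list[TaggedMolecule]) -> np.ndarray:
        packed = PackedGraphs.from_dags([build_rooted_dag(m) for m in tagged])
        return np.asarray(self.scaling.descale(packed.forward(self.params)))


def make_teacher(
    h: int = 8,
    seed: int = 0,
    state_dim: int = 1,
    library: SubstituentLibrary | None = None,
    ppm_window: tuple[float, float] = (100.0, 160.0),
) -> TeacherModel:
    """Teacher graph machine whose outputs span a realistic shift window."""
    params = teacher_parameters(h, seed, state_dim=state_dim)
    probe_seed = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    probe = generate_molecules(50, 4, probe_seed, library=library)
    tagged = [m for smi in probe for m in enumerate_ring_carbons(smi)]
    packed = PackedGraphs.from_dags([build_rooted_dag(m) for m in tagged])
    raw = packed.forward(params)
    lo, hi = float(raw.min()), float(raw.max())
    target_lo, target_hi = ppm_window
    if hi - lo < 1e-9:
        scaling = ScalingSpec(center=(target_lo + target_hi) / 2.0 - lo, half_range=1.0)
    else:
        k = (target_hi - target_lo) / (hi - lo)
        scaling = ScalingSpec(
            center=(target_lo + target_hi) / 2.0 - (lo + hi) / 2.0 * k,
            half_range=k,
        )
    return TeacherModel(params=params, scaling=scaling)


def make_dataset(
    n_molecules: int,
    noise_sd: float,
    seed,
    mode: str = "additive",
    max_substituents: int = 4,
    teacher_h: int = 8,
    teacher_state_dim: int = 1,
    teacher: TeacherModel | None = None,
    library: SubstituentLibrary | None = None,
) -> ShiftDataset:
    """Annotated ring carbons of ``n_molecules`` random benzenes.

    ``mode='additive'`` targets come from the increment oracle;
    ``mode='teacher'`` targets come from a fixed random graph machine
    (calibrated onto a realistic ppm window; pass ``teacher`` to reuse one
    across datasets, e.g. for held-out evaluation).  Gaussian noise with
    standard deviation ``noise_sd`` (ppm) is added in both modes.  Fully
    reproducible per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mode not in ("additive", "teacher"):
        raise ValueError(f"unknown mode {mode!r}")
    library = library or SubstituentLibrary.default()
    root = np.random.SeedSequence(entropy=seed)
    mol_seed, noise_seed, teacher_seed = root.spawn(3)
    smiles = generate_molecules(
        n_molecules, max_substituents, mol_seed, library=library
    )
    # one record per distinct carbon environment: symmetry-equivalent ring
    # carbons share a canonical tagged SMILES and a single shift, as in
    # experimental shift tables
    tagged: list[TaggedMolecule] = []
    seen: set[str] = set()
    for smi in smiles:
        for mol in enumerate_ring_carbons(smi):
            key = mol.canonical_tagged_smiles()
            if key not in seen:
                seen.add(key)
                tagged.append(mol)

    if mode == "additive":
        truth = np.array([additive_shift_oracle(m, library) for m in tagged])
    else:
        if teacher is None:
            teacher = make_teacher(
                teacher_h,
                int(teacher_seed.generate_state(1)[0] & 0x7FFFFFFF),
                state_dim=teacher_state_dim,
                library=library,
            )
        truth = teacher.predict(tagged)

    noise_rng = np.random.default_rng(noise_seed)
    targets = truth + noise_rng.normal(0.0, noise_sd, size=truth.size)
    return ShiftDataset(records=list(zip(tagged, targets.tolist())))
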