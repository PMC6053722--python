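"""Synthetic structures and graphs with planted ground truth.

Every pipeline stage can be exercised without downloading anything: ideal
helices stand in for crystal structures, controlled per-residue perturbations
plant known displacements, template side chains (lysine, glutamate,
cysteine...) let multi-chain complexes realize designed typed contacts, and
small graphs with hand-traceable MCODE outcomes drive the clustering tests.

Generators are deterministic: the same spec (and seed, where randomness is
requested) yields byte-identical PDB output, and each generator returns its
ground truth alongside the model so tests assert *recovery*, never
re-derivation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np

from rincompare.rin_mcode import ContactNetwork
from rincompare.structure_io import AtomSite, ResidueSite, StructureModel
from rincompare.superpose import RigidTransform

__all__ = [
    "HelixSpec",
    "PerturbationSpec",
    "ComplexSpec",
    "make_ideal_helix",
    "perturb_residues",
    "contact_probe",
    "make_complex",
    "make_rin_fixture",
]


@dataclass
class HelixSpec:
    """Ideal helix parameters: Calpha on a circular helix of given radius
    (Å), rise per residue (Å) and twist per residue (degrees), plus one
    radially offset pseudo side-chain atom per residue.  The defaults give
    the ~3.8 Å consecutive Calpha spacing of real protein helices."""

    n_residues: int = 10
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    chain_id: str = "A"
    first_seq_number: int = 1
    b_profile: Union[float, Dict[int, float]] = 15.0
    res_name: str = "ALA"

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("helix needs at least 2 residues")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")

    def b_for(self, seq_number: int) -> float:
        if isinstance(self.b_profile, dict):
            return float(self.b_profile.get(seq_number, 15.0))
        return float(self.b_profile)


def make_ideal_helix(spec: HelixSpec) -> StructureModel:
    """Build an ideal helix: Calpha i at (r·cos(iθ), r·sin(iθ), i·rise),
    with a pseudo side-chain atom (CB) offset 1.5 Å radially outward."""
    theta = np.radians(spec.twist)
    residues = []
    serial = 1
    for i in range(spec.n_residues):
        seq = spec.first_seq_number + i
        ca = np.array(
            [spec.radius * np.cos(i * theta), spec.radius * np.sin(i * theta), i * spec.rise]
        )
        radial = np.array([np.cos(i * theta), np.sin(i * theta), 0.0])
        cb = ca + 1.5 * radial
        b = spec.b_for(seq)
        atoms = [
            AtomSite(serial=serial, name="CA", element="C", coords=ca, b_factor=b),
            AtomSite(serial=serial + 1, name="CB", element="C", coords=cb, b_factor=b),
        ]
        serial += 2
        residues.append(
            ResidueSite(
                chain_id=spec.chain_id,
                seq_number=seq,
                insertion_code="",
                res_name=spec.res_name,
                atoms=atoms,
            )
        )
    return StructureModel(id=f"helix_{spec.chain_id}{spec.n_residues}", chains={spec.chain_id: residues})


@dataclass
class PerturbationSpec:
    """Translate all atoms of each target residue by displacement·direction.

    ``direction`` is a 3-vector (normalized internally) or the string
    ``"random"``, in which case a unit vector is drawn per residue from the
    seeded generator."""

    target_residues: Set[int] = field(default_factory=set)
    displacement: float = 0.0
    direction: Union[str, Sequence[float]] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")


def perturb_residues(model: StructureModel, spec: PerturbationSpec) -> StructureModel:
    """Return a copy of *model* with the target residues rigidly translated."""
    out = copy.deepcopy(model)
    out.id = f"{model.id}_perturbed"
    rng = np.random.default_rng(spec.seed)
    available = {r.seq_number for r in out.residues()}
    missing = set(spec.target_residues) - available
    if missing:
        raise KeyError(f"target residues not in model: {sorted(missing)}")
    for res in out.residues():
        if res.seq_number not in spec.target_residues:
            continue
        if isinstance(spec.direction, str):
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        else:
            direction = np.asarray(spec.direction, dtype=float)
            direction = direction / np.linalg.norm(direction)
        shift = spec.displacement * direction
        for a in res.atoms:
            a.coords = a.coords + shift
    return out


# --- template side chains for typed-contact probes -------------------------

# heavy-atom chains built outward from CA; the last atom is the "key" atom
# placed exactly at the requested position by contact_probe()
_PROBE_TEMPLATES = {
    "LYS": ("N", "CA", "CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("N", "CA", "CB", "CG", "CD", "NE", "CZ", "NH1"),
    "GLU": ("N", "CA", "CB", "CG", "CD", "OE1"),
    "CYS": ("N", "CA", "CB", "SG"),
    "ALA": ("N", "CA", "CB"),
}
_ELEMENTS = {"N": "N", "CA": "C", "CB": "C", "CG": "C", "CD": "C", "CE": "C",
             "NZ": "N", "NE": "N", "CZ": "C", "NH1": "N",
             "OE1": "O", "OE2": "O", "SG": "S"}


def contact_probe(
    res_name: str,
    chain_id: str,
    seq_number: int,
    key_atom_pos: Sequence[float],
    direction: Sequence[float] = (1.0, 0.0, 0.0),
    b_factor: float = 15.0,
) -> ResidueSite:
    """One residue whose chemically active ("key") atom sits exactly at
    *key_atom_pos*, the rest of the chain trailing opposite *direction* at
    1.5 Å spacing.  Used to design complexes with exact contact geometry."""
    names = _PROBE_TEMPLATES[res_name]
    pos = np.asarray(key_atom_pos, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # slight perpendicular zig-zag so the residue is not exactly collinear
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    atoms = []
    n = len(names)
    for i, name in enumerate(names):
        back = (n - 1 - i)
        coords = pos - d * 1.5 * back + perp * (0.4 if (back % 2) else 0.0)
        atoms.append(
            AtomSite(
                serial=i + 1,
                name=name,
                element=_ELEMENTS[name],
                coords=coords,
                b_factor=b_factor,
            )
        )
    if res_name == "GLU":  # carboxylate has two oxygens; OE2 sits behind OE1
        oe1 = atoms[-1].coords
        atoms.append(
            AtomSite(serial=len(atoms) + 1, name="OE2", element="O",
                     coords=oe1 + perp * 1.1 - d * 0.4, b_factor=b_factor)
        )
    return ResidueSite(
        chain_id=chain_id,
        seq_number=seq_number,
        insertion_code="",
        res_name=res_name,
        atoms=atoms,
    )


@dataclass
class ComplexSpec:
    """Components, rigid placements, and designed inter-chain contacts.

    ``designed_contacts`` entries are ((chain, seq, atom), (chain, seq, atom),
    target distance in Å); after placement each must hold within 0.05 Å.
    """

    components: List[StructureModel] = field(default_factory=list)
    placements: List[RigidTransform] = field(default_factory=list)
    designed_contacts: List[Tuple[Tuple[str, int, str], Tuple[str, int, str], float]] = field(
        default_factory=list
    )
    contact_tolerance: float = 0.05
    clash_distance: float = 2.0
    id: str = "complex"


def _find_atom(model: StructureModel, chain: str, seq: int, atom: str) -> AtomSite:
    res = model.residue((chain, seq, ""))
    a = res.atom(atom)
    if a is None:
        raise KeyError(f"atom {atom} not in residue {chain}:{seq}")
    return a


def make_complex(spec: ComplexSpec) -> StructureModel:
    """Assemble a multi-chain complex from rigidly placed components.

    Raises if chain ids collide, a designed contact is not achieved within
    tolerance, or an undesigned inter-chain heavy-atom pair clashes
    (closer than ``clash_distance``).
    """
    if len(spec.components) != len(spec.placements):
        raise ValueError("one placement per component required")
    chains: Dict[str, list] = {}
    for comp, placement in zip(spec.components, spec.placements):
        moved = copy.deepcopy(comp)
        for res in moved.residues():
            for a in res.atoms:
                a.coords = placement.apply(a.coords)
        for cid, residues in moved.chains.items():
            if cid in chains:
                raise ValueError(f"duplicate chain id {cid!r} in complex")
            chains[cid] = residues
    merged = StructureModel(id=spec.id, chains=chains)

    designed_atoms = set()
    for (ca_, sa, aa), (cb_, sb, ab), target in spec.designed_contacts:
        atom_a = _find_atom(merged, ca_, sa, aa)
        atom_b = _find_atom(merged, cb_, sb, ab)
        d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
        if abs(d - target) > spec.contact_tolerance:
            raise ValueError(
                f"designed contact {ca_}:{sa}:{aa}–{cb_}:{sb}:{ab} is {d:.3f} Å, "
                f"target {target:.3f} Å"
            )
        designed_atoms.add((ca_, sa, aa))
        designed_atoms.add((cb_, sb, ab))

    # clash scan over undesigned inter-chain heavy-atom pairs
    flat = [
        (r.chain_id, r.seq_number, a.name, a.coords)
        for r in merged.residues()
        for a in r.heavy_atoms()
    ]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if flat[i][0] == flat[j][0]:
                continue
            if (flat[i][:3] in designed_atoms) and (flat[j][:3] in designed_atoms):
                continue
            if float(np.linalg.norm(flat[i][3] - flat[j][3])) < spec.clash_distance:
                raise ValueError(
                    f"undesigned clash between {flat[i][:3]} and {flat[j][:3]}"
                )
    return merged


def make_rin_fixture(kind: str) -> Tuple[ContactNetwork, dict]:
    """Small graphs with known MCODE outcomes.

    kinds: ``clique_plus_tail`` (K6 with a 3-node tail — one cluster, the
    K6, score 6.0), ``path`` (P6 — no cluster at min score 5), and
    ``planted_dense_block`` (K6 embedded in a 20-node sparse ring — the
    block is recovered exactly).  Returns (network, truth record).
    """
    g = nx.Graph()
    if kind == "clique_plus_tail":
        g.add_edges_from((i, j) for i in range(6) for j in range(i + 1, 6))
        g.add_edges_from([(5, 6), (6, 7), (7, 8)])
        truth = {"clusters": [{"members": set(range(6)), "score": 6.0}]}
    elif kind == "path":
        g.add_edges_from((i, i + 1) for i in range(5))
        truth = {"clusters": []}
    elif kind == "planted_dense_block":
        n_ring = 20
        g.add_edges_from((i, (i + 1) % n_ring) for i in range(n_ring))
        block = range(8, 14)
        g.add_edges_from((i, j) for i in block for j in block if i < j)
        truth = {"clusters": [{"members": set(block), "score": 6.0}]}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    for v in g.nodes:
        g.nodes[v]["residue_key"] = ("A", v, "")
        g.nodes[v]["resnum"] = v
        g.nodes[v]["resname"] = "GLY"
    net = ContactNetwork(graph=g, cutoff=float("inf"), structure_id=f"fixture:{kind}")
    return net, truth
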