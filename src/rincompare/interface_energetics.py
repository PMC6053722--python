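"""Typed non-covalent contact detection and interface energy accounting.

Residue–residue interactions in a (multi-chain) structure are detected from
geometry alone, typed as hydrogen bond, ionic (salt bridge), disulfide,
π–π stack, π–cation, or van der Waals contact, and assigned an empirical
per-type energy.  For a docked complex the interprotein (inter-chain) edges
are then tallied — total count and total energy, and the share contributed
by a configurable set of residues of interest — mirroring the dimer/trimer
interface accounting used in the lysozyme amyloid study, where the residues
of interest default to {21, 62, 104, 112–117, 122}.

The per-type distance thresholds and energies follow the "strict"
conventions of standard residue-interaction-network generators; they are
plain data on :class:`InteractionConfig` and can be edited freely.  Energy
totals are therefore only comparable between runs sharing a config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from rincompare.structure_io import ResidueKey, ResidueSite, StructureModel

__all__ = [
    "InteractionEdge",
    "InteractionConfig",
    "ResiduesOfInterest",
    "InterfaceSummary",
    "detect_interactions",
    "interprotein_summary",
    "summarize_report_row",
    "edges_tsv",
]

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("HBOND", "IONIC", "SSBOND", "PIPISTACK", "PICATION", "VDW")

# --- residue chemistry tables (heavy atoms only) ---------------------------

POSITIVE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
# C-terminal carboxylate oxygen counts as negative for any residue
NEGATIVE_ANY = ("OXT",)

HB_DONORS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "CYS": ("SG",),
}
HB_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}
BACKBONE_DONOR = "N"  # except proline
BACKBONE_ACCEPTORS = ("O", "OXT")

AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("CZ",)}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.10}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class InteractionEdge:
    """One typed interaction between two residues, with its closest-atom
    distance (Å) and the configured energy magnitude (kJ/mol)."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    type: str
    distance: float
    energy: float

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("self-interaction edge")
        if self.type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.type!r}")

    @property
    def inter_chain(self) -> bool:
        return self.residue_a[0] != self.residue_b[0]


def _default_thresholds() -> Dict[str, float]:
    return {
        "HBOND": 3.5,
        "IONIC": 4.0,
        "SSBOND": 2.5,
        "PIPISTACK": 6.5,
        "PICATION": 5.0,
        "VDW": 0.5,  # tolerance added to the sum of van der Waals radii
    }


def _default_energies() -> Dict[str, float]:
    return {
        "HBOND": 17.0,
        "IONIC": 20.0,
        "SSBOND": 167.0,
        "PIPISTACK": 9.4,
        "PICATION": 9.6,
        "VDW": 6.0,
    }


def _default_angles() -> Dict[str, float]:
    return {
        "HBOND_DONOR_MIN": 90.0,  # D–H...A angle lower bound, applied when H present
        "PIPISTACK_PARALLEL_MAX": 30.0,
        "PIPISTACK_TSHAPE_MIN": 60.0,
        "PICATION_MAX": 45.0,
    }


@dataclass
class InteractionConfig:
    """Editable detection table: per-type distance thresholds (Å), angle
    limits (degrees) and energies (kJ/mol), plus the intra-chain sequence
    separation rule (pairs closer than ``min_sequence_separation + 1`` in
    sequence are ignored; inter-chain pairs are exempt)."""

    thresholds: Dict[str, float] = field(default_factory=_default_thresholds)
    energies: Dict[str, float] = field(default_factory=_default_energies)
    angles: Dict[str, float] = field(default_factory=_default_angles)
    min_sequence_separation: int = 2
    closest_atom_rule: str = "strict"

    def __post_init__(self) -> None:
        for name, value in {**self.thresholds, **self.energies}.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass
class ResiduesOfInterest:
    """Author residue numbers whose interface contribution is reported."""

    residues: Set[int] = field(
        default_factory=lambda: {21, 62, 104, 112, 113, 114, 115, 116, 117, 122}
    )
    match_rule: str = "either_endpoint"  # or "both_endpoints"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues-of-interest set must be non-empty")
        if self.match_rule not in ("either_endpoint", "both_endpoints"):
            raise ValueError(f"unknown match_rule {self.match_rule!r}")

    def matches(self, edge: InteractionEdge) -> bool:
        a_in = edge.residue_a[1] in self.residues
        b_in = edge.residue_b[1] in self.residues
        return (a_in and b_in) if self.match_rule == "both_endpoints" else (a_in or b_in)


@dataclass
class InterfaceSummary:
    """Interprotein interaction totals and residues-of-interest shares."""

    n_total: int
    e_total: float
    n_roi: int
    e_roi: float
    pct_n_roi: float
    pct_e_roi: float
    per_type_breakdown: Dict[str, Tuple[int, float]]


def _percent(part: float, whole: float) -> float:
    """100·part/whole rounded half-up to one decimal; 0.0 for an empty whole."""
    if whole == 0:
        return 0.0
    return float(
        Decimal(repr(100.0 * part / whole)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def _ring_geometry(res: ResidueSite):
    names = AROMATIC_RINGS.get(res.res_name)
    if not names:
        return None
    coords = [res.atom(n).coords for n in names if res.atom(n) is not None]
    if len(coords) < 4:
        return None
    xyz = np.array(coords)
    centroid = xyz.mean(axis=0)
    # ring normal: smallest principal axis of the ring atoms
    _, _, vt = np.linalg.svd(xyz - centroid)
    return centroid, vt[2]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(
        abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))), 0.0, 1.0
    )
    return float(np.degrees(np.arccos(cosang)))


def _charged_atoms(res: ResidueSite, sign: str) -> List:
    if sign == "+":
        names = POSITIVE_ATOMS.get(res.res_name, ())
        return [a for n in names if (a := res.atom(n)) is not None]
    names = NEGATIVE_ATOMS.get(res.res_name, ()) + NEGATIVE_ANY
    return [a for n in names if (a := res.atom(n)) is not None]


def _donor_atoms(res: ResidueSite) -> List:
    atoms = []
    if res.res_name != "PRO" and (bb := res.atom(BACKBONE_DONOR)) is not None:
        atoms.append(bb)
    for n in HB_DONORS.get(res.res_name, ()):
        if (a := res.atom(n)) is not None:
            atoms.append(a)
    return atoms


def _acceptor_atoms(res: ResidueSite) -> List:
    atoms = [a for n in BACKBONE_ACCEPTORS if (a := res.atom(n)) is not None]
    for n in HB_ACCEPTORS.get(res.res_name, ()):
        if (a := res.atom(n)) is not None:
            atoms.append(a)
    return atoms


def _min_pair_distance(atoms_a: Sequence, atoms_b: Sequence) -> Optional[float]:
    if not atoms_a or not atoms_b:
        return None
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return float(d.min())


def _hbond_distance(res_a: ResidueSite, res_b: ResidueSite, config: InteractionConfig):
    """Best qualifying donor→acceptor heavy-atom distance across both
    directions, honoring the donor angle when hydrogens are present."""
    limit = config.thresholds["HBOND"]
    best = None
    for donor_res, acceptor_res in ((res_a, res_b), (res_b, res_a)):
        for d in _donor_atoms(donor_res):
            hydrogens = [
                h for h in donor_res.atoms
                if h.is_hydrogen and np.linalg.norm(h.coords - d.coords) < 1.3
            ]
            for acc in _acceptor_atoms(acceptor_res):
                dist = float(np.linalg.norm(d.coords - acc.coords))
                if dist > limit or dist < 2.0:
                    continue
                if hydrogens and not any(
                    _dha_angle(d.coords, h.coords, acc.coords)
                    >= config.angles["HBOND_DONOR_MIN"]
                    for h in hydrogens
                ):
                    continue
                if best is None or dist < best:
                    best = dist
    return best


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    u, v = d - h, a - h
    cosang = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _detect_pair(
    res_a: ResidueSite, res_b: ResidueSite, config: InteractionConfig
) -> List[InteractionEdge]:
    edges: List[Tuple[str, float]] = []
    thr, ang = config.thresholds, config.angles

    # IONIC: opposite formal charges within threshold
    ionic = None
    for sa, sb in (("+", "-"), ("-", "+")):
        d = _min_pair_distance(_charged_atoms(res_a, sa), _charged_atoms(res_b, sb))
        if d is not None and d <= thr["IONIC"] and (ionic is None or d < ionic):
            ionic = d
    if ionic is not None:
        edges.append(("IONIC", ionic))

    # HBOND
    hb = _hbond_distance(res_a, res_b, config)
    if hb is not None:
        edges.append(("HBOND", hb))

    # SSBOND
    if res_a.res_name == "CYS" and res_b.res_name == "CYS":
        sg_a, sg_b = res_a.atom("SG"), res_b.atom("SG")
        if sg_a is not None and sg_b is not None:
            d = float(np.linalg.norm(sg_a.coords - sg_b.coords))
            if d <= thr["SSBOND"]:
                edges.append(("SSBOND", d))

    # PIPISTACK
    ring_a, ring_b = _ring_geometry(res_a), _ring_geometry(res_b)
    if ring_a is not None and ring_b is not None:
        d = float(np.linalg.norm(ring_a[0] - ring_b[0]))
        if d <= thr["PIPISTACK"]:
            theta = _angle_deg(ring_a[1], ring_b[1])
            if theta <= ang["PIPISTACK_PARALLEL_MAX"] or theta >= ang["PIPISTACK_TSHAPE_MIN"]:
                edges.append(("PIPISTACK", d))

    # PICATION
    for ring_res, cat_res in ((res_a, res_b), (res_b, res_a)):
        ring = _ring_geometry(ring_res)
        if ring is None:
            continue
        cations = [
            a for n in CATION_ATOMS.get(cat_res.res_name, ()) if (a := cat_res.atom(n)) is not None
        ]
        for cat in cations:
            d = float(np.linalg.norm(ring[0] - cat.coords))
            if d <= thr["PICATION"] and _angle_deg(ring[1], cat.coords - ring[0]) <= ang["PICATION_MAX"]:
                existing = [e for e in edges if e[0] == "PICATION"]
                if not existing or d < existing[0][1]:
                    edges = [e for e in edges if e[0] != "PICATION"] + [("PICATION", d)]

    # VDW fallback: only when no specific type fired for this pair
    if not edges:
        best = None
        for a in res_a.heavy_atoms():
            ra = VDW_RADII.get(a.element.upper(), DEFAULT_VDW_RADIUS)
            for b in res_b.heavy_atoms():
                rb = VDW_RADII.get(b.element.upper(), DEFAULT_VDW_RADIUS)
                d = float(np.linalg.norm(a.coords - b.coords))
                if d <= ra + rb + thr["VDW"] and (best is None or d < best):
                    best = d
        if best is not None:
            edges.append(("VDW", best))

    return [
        InteractionEdge(
            residue_a=res_a.key,
            residue_b=res_b.key,
            type=t,
            distance=d,
            energy=config.energies[t],
        )
        for t, d in edges
    ]


STANDARD_RESIDUES = set(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def detect_interactions(
    complex_model: StructureModel, config: InteractionConfig | None = None
) -> List[InteractionEdge]:
    """Detect all typed residue–residue interactions in a structure.

    Intra-chain pairs must be separated by more than
    ``config.min_sequence_separation`` residues; inter-chain pairs are always
    eligible.  At most one edge per (pair, type) is emitted, carrying the
    minimal qualifying distance.  Residues whose name is not a standard
    amino acid are skipped for charge/ring typing and logged.
    """
    config = config or InteractionConfig()
    residues = []
    for r in complex_model.residues():
        if r.res_name not in STANDARD_RESIDUES:
            logger.info("residue %s (%s): unknown chemistry, skipped", r.key, r.res_name)
            continue
        residues.append(r)

    # coarse candidate screen on heavy-atom KD-tree
    atom_coords, atom_res = [], []
    for idx, r in enumerate(residues):
        for a in r.heavy_atoms():
            atom_coords.append(a.coords)
            atom_res.append(idx)
    if not atom_coords:
        return []
    tree = cKDTree(np.array(atom_coords))
    reach = max(config.thresholds["PIPISTACK"], config.thresholds["IONIC"],
                config.thresholds["HBOND"], 8.0)
    candidate_pairs = set()
    for ia, ib in tree.query_pairs(reach):
        ra, rb = atom_res[ia], atom_res[ib]
        if ra != rb:
            candidate_pairs.add((min(ra, rb), max(ra, rb)))

    edges: List[InteractionEdge] = []
    for ia, ib in sorted(candidate_pairs):
        res_a, res_b = residues[ia], residues[ib]
        if res_a.chain_id == res_b.chain_id:
            if abs(res_a.seq_number - res_b.seq_number) <= config.min_sequence_separation:
                continue
        edges.extend(_detect_pair(res_a, res_b, config))
    return edges


def interprotein_summary(
    edges: Iterable[InteractionEdge], roi: ResiduesOfInterest | None = None
) -> InterfaceSummary:
    """Tally interprotein (inter-chain) interactions and the share carried by
    the residues of interest.  Percentages are rounded half-up to one
    decimal, matching printed interface tables."""
    roi = roi or ResiduesOfInterest()
    inter = [e for e in edges if e.inter_chain]
    n_total = len(inter)
    e_total = float(sum(e.energy for e in inter))
    roi_edges = [e for e in inter if roi.matches(e)]
    n_roi = len(roi_edges)
    e_roi = float(sum(e.energy for e in roi_edges))
    breakdown: Dict[str, Tuple[int, float]] = {}
    for t in INTERACTION_TYPES:
        typed = [e for e in inter if e.type == t]
        if typed:
            breakdown[t] = (len(typed), float(sum(e.energy for e in typed)))
    return InterfaceSummary(
        n_total=n_total,
        e_total=e_total,
        n_roi=n_roi,
        e_roi=e_roi,
        pct_n_roi=_percent(n_roi, n_total),
        pct_e_roi=_percent(e_roi, e_total),
        per_type_breakdown=breakdown,
    )


def summarize_report_row(
    n_total: int, e_total: float, n_roi: int, e_roi: float
) -> Dict[str, float]:
    """Interface-table row arithmetic from pre-tallied totals.

    Returns counts, energies and the residues-of-interest percentages rounded
    half-up to one decimal — e.g. (89, 824.8, 2, 12) → 2.2% of interactions
    and 1.5% of the bond energy.
    """
    if n_roi > n_total or e_roi > e_total:
        raise ValueError("residues-of-interest tallies exceed the totals")
    return {
        "n_total": n_total,
        "e_total": e_total,
        "n_roi": n_roi,
        "e_roi": e_roi,
        "pct_n_roi": _percent(n_roi, n_total),
        "pct_e_roi": _percent(e_roi, e_total),
    }


def edges_tsv(edges: Sequence[InteractionEdge]) -> str:
    """TSV: chainA, resA, chainB, resB, type, distance, energy."""
    lines = ["chain_a\tres_a\tchain_b\tres_b\ttype\tdistance_A\tenergy_kJ_mol"]
    for e in sorted(edges, key=lambda e: (e.residue_a, e.residue_b, e.type)):
        lines.append(
            f"{e.residue_a[0]}\t{e.residue_a[1]}{e.residue_a[2]}\t"
            f"{e.residue_b[0]}\t{e.residue_b[1]}{e.residue_b[2]}\t"
            f"{e.type}\t{e.distance:.2f}\t{e.energy:.1f}"
        )
    return "\n".join(lines) + "\n"
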