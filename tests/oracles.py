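"""Independent reference implementations used only as test oracles.

These are deliberately naive and written from the published definitions,
separately from the package's code paths: a brute-force k-core/density
MCODE, a quaternion-eigenvalue rigid fit, and a brute-force PDB ATOM-record
scanner.  They trade speed for obviousness.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np


# --- naive MCODE -----------------------------------------------------------

def naive_density(g: nx.Graph, nodes) -> float:
    nodes = list(nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    e = 0
    for i in range(n):
        for j in range(i + 1, n):
            if g.has_edge(nodes[i], nodes[j]):
                e += 1
    return 2.0 * e / (n * (n - 1))


def naive_k_core(g: nx.Graph, nodes: Set, k: int) -> Set:
    """Members of the k-core of the induced subgraph, by repeated stripping."""
    nodes = set(nodes)
    while True:
        weak = {
            v for v in nodes if sum(1 for u in g.neighbors(v) if u in nodes) < k
        }
        if not weak:
            return nodes
        nodes -= weak


def naive_vertex_weight(g: nx.Graph, v, degree_cutoff: int = 2) -> float:
    if g.degree(v) < degree_cutoff:
        return 0.0
    closed = set(g.neighbors(v)) | {v}
    best_k, best_core = 0, set()
    k = 1
    while True:
        core = naive_k_core(g, closed, k)
        if not core:
            break
        best_k, best_core = k, core
        k += 1
    return best_k * naive_density(g, best_core)


def naive_mcode(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core_filter: int = 2,
    haircut: bool = True,
    min_cluster_score: float = 5.0,
) -> List[Tuple[Set, float]]:
    """Clusters as (member set, score), ranked (score desc, min member asc).

    Follows the published procedure: seed at the highest-weight unassigned
    vertex (ties to the smaller node), grow by including neighbors whose
    weight is at least seed_weight*(1 - cutoff), then 2-core filter and
    haircut, dropping small or low-scoring clusters.
    """
    weights = {v: naive_vertex_weight(g, v, degree_cutoff) for v in g}
    assigned: Set = set()
    found = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - node_score_cutoff)
        members = {seed}
        grew = True
        while grew:
            grew = False
            for v in list(members):
                for u in g.neighbors(v):
                    if u not in members and u not in assigned and weights[u] >= threshold:
                        members.add(u)
                        grew = True
        assigned |= members
        if k_core_filter > 0 and not naive_k_core(g, members, k_core_filter):
            continue
        final = naive_k_core(g, members, 2) if haircut else members
        if len(final) < 2:
            continue
        score = naive_density(g, final) * len(final)
        if score < min_cluster_score:
            continue
        found.append((final, score))
    found.sort(key=lambda item: (-item[1], min(item[0])))
    return found


# --- quaternion-eigenvalue rigid fit (Horn's method) -----------------------

def quaternion_fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = float((Pc**2).sum() + (Qc**2).sum() - 2.0 * lam)
    return float(np.sqrt(max(ssd, 0.0) / len(P)))


def quaternion_fit_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix from the dominant eigenvector quaternion."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q0, q1, q2, q3 = v[:, -1]
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )


# --- brute-force PDB scanners ---------------------------------------------

def scan_atom_records(text: str) -> int:
    """Count retained ATOM records the way the parser should: first MODEL
    only, one atom per (residue, atom name) alt-loc group."""
    keys = set()
    for line in text.splitlines():
        if line.startswith("ENDMDL"):
            break
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        chain = line[21]
        resseq = line[22:26].strip()
        icode = line[26].strip()
        keys.add((chain, resseq, icode, name))
    return len(keys)


def scan_residue_keys(text: str) -> Set[Tuple[str, str, str]]:
    """Unique (chain, resSeq, iCode) keys over ATOM records, first model."""
    keys = set()
    for line in text.splitlines():
        if line.startswith("ENDMDL"):
            break
        if line.startswith("ATOM"):
            keys.add((line[21], line[22:26].strip(), line[26].strip()))
    return keys
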