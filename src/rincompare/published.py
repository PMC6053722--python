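"""Literature-reported values for the human lysozyme native-state study.

These are the printed results of the published comparison of WT human
lysozyme (PDB 1REX) with its amyloidogenic variants I56T (1LOZ) and D67H
(1LYY): the per-structure MCODE cluster table (rank, score, member residues,
cluster-average B-factor) and the interprotein interface totals for the
docked homodimer/homotrimer/heterodimer models.  They serve as *inputs* to
desk-scale computations — the score/B-factor correlation and the interface
percentage arithmetic — and as expected values in regression tests; nothing
here is produced by this package.

Note on the cluster table: the printed rank-1 rows carry an extra numeric
field of unclear meaning (4.88, 6.06, 3.24); the scores recorded here
(6.36, 6.00, 6.50) are the parse that exactly reproduces the published
correlation r² = 0.44, p = 0.0184.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Residues identified as displaced (RMSD ≥ 1.9 Å) in both variants.
SHARED_DISPLACED_RESIDUES = frozenset({21, 62, 104, 122})

#: The full residues-of-interest set: displaced residues plus the 112–117
#: cluster whose density increases in both variants.
RESIDUES_OF_INTEREST = frozenset({21, 62, 104, 112, 113, 114, 115, 116, 117, 122})

#: Per-structure retained MCODE clusters:
#: (rank, MCODE score, member residues, cluster-average B-factor in Å²)
CLUSTER_TABLE: Dict[str, List[Tuple[int, float, Tuple[int, ...], float]]] = {
    "1rex": [
        (1, 6.36, tuple(range(92, 104)), 12.35),
        (2, 6.00, tuple(range(32, 38)), 11.71),
        (3, 5.60, tuple(range(7, 14)) + (19,) + tuple(range(23, 30)) + (31,), 9.72),
        (4, 5.11, (104, 106, 107, 108) + tuple(range(112, 118)), 19.09),
    ],
    "1loz": [
        (1, 6.00, tuple(range(112, 118)), 17.53),
        (2, 6.00, tuple(range(92, 99)), 10.54),
        (3, 5.60, tuple(range(7, 14)) + (19,) + tuple(range(23, 30)) + (31,), 10.39),
        (4, 5.00, tuple(range(122, 127)), 29.15),
    ],
    "1lyy": [
        (1, 6.50, tuple(range(92, 101)), 7.83),
        (2, 6.00, tuple(range(112, 118)), 14.99),
        (3, 6.00, tuple(range(32, 38)), 8.21),
        (4, 5.75, tuple(range(7, 14)) + (17, 18, 19) + (23,) + tuple(range(25, 30)) + (31,), 8.12),
    ],
}


def cluster_score_bfactor_pairs() -> List[Tuple[float, float]]:
    """The 12 (MCODE score, cluster-average B-factor) pairs of the published
    cluster table, in structure-then-rank order."""
    return [
        (score, avg_b)
        for sid in ("1rex", "1loz", "1lyy")
        for (_rank, score, _members, avg_b) in CLUSTER_TABLE[sid]
    ]


#: Interface totals for the top-ranked docked models:
#: (n_total, roi count, e_total kJ/mol, roi energy kJ/mol) and the printed
#: one-decimal percentages for the residues-of-interest shares.
INTERFACE_TOTALS: Dict[str, Dict[str, tuple]] = {
    "homodimer": {
        "WT": (100, 36, 1019.0, 398.0, 36.0, 39.1),
        "I56T": (71, 35, 768.0, 442.0, 49.3, 57.6),
        "D67H": (61, 18, 594.6, 246.0, 29.5, 41.4),
    },
    "homotrimer": {
        "WT": (89, 2, 824.8, 12.0, 2.2, 1.5),
        "I56T": (133, 74, 1392.8, 817.0, 55.6, 58.7),
        "D67H": (108, 24, 1060.8, 320.0, 22.2, 30.2),
    },
    "heterodimer": {
        "WT:I56T": (48, 25, 481.0, 238.0, 52.1, 49.5),
        "WT:D67H": (49, 27, 482.6, 289.6, 55.1, 60.0),
    },
}

#: Published correlation over the 12 cluster (score, B) pairs.
PUBLISHED_R_SQUARED = 0.44
PUBLISHED_P_VALUE = 0.0184
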