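"""Typed contact detection and interprotein interface accounting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rincompare.interface_energetics import (
    InteractionConfig,
    InteractionEdge,
    InterfaceSummary,
    ResiduesOfInterest,
    detect_interactions,
    interprotein_summary,
    summarize_report_row,
)
from rincompare.published import INTERFACE_TOTALS
from rincompare.structure_io import StructureModel
from rincompare.superpose import RigidTransform
from rincompare.synthetic_structures import ComplexSpec, contact_probe, make_complex


def two_chain_model(res_a, res_b, model_id="pair"):
    return StructureModel(id=model_id, chains={res_a.chain_id: [res_a], res_b.chain_id: [res_b]})


class TestDetectInteractions:
    def test_distant_chains_no_edges(self):
        m = two_chain_model(
            contact_probe("LYS", "A", 1, (0, 0, 0)),
            contact_probe("GLU", "B", 2, (50, 0, 0)),
        )
        assert detect_interactions(m) == []

    def test_designed_salt_bridge(self):
        m = two_chain_model(
            contact_probe("LYS", "A", 10, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("GLU", "B", 20, (3.0, 0, 0), direction=(-1, 0, 0)),
        )
        edges = detect_interactions(m)
        ionic = [e for e in edges if e.type == "IONIC"]
        assert len(ionic) == 1
        assert ionic[0].distance == pytest.approx(3.0, abs=1e-6)
        assert ionic[0].inter_chain

    def test_designed_disulfide(self):
        m = two_chain_model(
            contact_probe("CYS", "A", 1, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("CYS", "B", 2, (2.05, 0, 0), direction=(-1, 0, 0)),
        )
        edges = detect_interactions(m)
        assert [e.type for e in edges] == ["SSBOND"]
        assert edges[0].distance == pytest.approx(2.05, abs=1e-6)

    def test_vdw_only_when_no_specific_type(self):
        m = two_chain_model(
            contact_probe("ALA", "A", 1, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("ALA", "B", 2, (3.6, 0, 0), direction=(-1, 0, 0)),
        )
        edges = detect_interactions(m)
        assert [e.type for e in edges] == ["VDW"]
        # a pair that hydrogen-bonds must not also produce a VDW edge
        m2 = two_chain_model(
            contact_probe("LYS", "A", 10, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("GLU", "B", 20, (3.0, 0, 0), direction=(-1, 0, 0)),
        )
        assert "VDW" not in {e.type for e in detect_interactions(m2)}

    def test_intra_chain_sequence_separation(self):
        close = contact_probe("LYS", "A", 10, (0, 0, 0), direction=(1, 0, 0))
        neighbor = contact_probe("GLU", "A", 12, (3.0, 0, 0), direction=(-1, 0, 0))
        spaced = contact_probe("GLU", "A", 13, (3.0, 0, 0), direction=(-1, 0, 0))
        m_close = StructureModel(id="x", chains={"A": [close, neighbor]})
        m_far = StructureModel(id="y", chains={"A": [close, spaced]})
        assert detect_interactions(m_close) == []
        assert any(e.type == "IONIC" for e in detect_interactions(m_far))

    def test_one_edge_per_pair_and_type(self):
        # several candidate atom pairs still yield a single IONIC edge
        m = two_chain_model(
            contact_probe("ARG", "A", 5, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("GLU", "B", 6, (3.2, 0, 0), direction=(-1, 0, 0)),
        )
        edges = detect_interactions(m)
        seen = [(e.residue_a, e.residue_b, e.type) for e in edges]
        assert len(seen) == len(set(seen))

    def test_threshold_monotonicity(self):
        m = two_chain_model(
            contact_probe("LYS", "A", 10, (0, 0, 0), direction=(1, 0, 0)),
            contact_probe("GLU", "B", 20, (4.5, 0, 0), direction=(-1, 0, 0)),
        )
        tight = detect_interactions(m)
        loose_cfg = InteractionConfig()
        loose_cfg.thresholds["IONIC"] = 6.0
        loose_cfg.thresholds["HBOND"] = 6.0
        loose = detect_interactions(m, loose_cfg)
        assert len(loose) >= len(tight)
        assert any(e.type == "IONIC" for e in loose)

    def test_nonstandard_residue_skipped(self):
        probe = contact_probe("LYS", "A", 1, (0, 0, 0))
        weird = contact_probe("ALA", "B", 2, (3.0, 0, 0), direction=(-1, 0, 0))
        weird.res_name = "XYZ"
        m = two_chain_model(probe, weird)
        assert detect_interactions(m) == []


class TestMakeComplexIntegration:
    def test_designed_ionic_contact_via_complex_spec(self):
        lys = StructureModel(
            id="a", chains={"A": [contact_probe("LYS", "A", 21, (0, 0, 0), direction=(1, 0, 0))]}
        )
        glu = StructureModel(
            id="b", chains={"B": [contact_probe("GLU", "B", 40, (3.0, 0, 0), direction=(-1, 0, 0))]}
        )
        complex_model = make_complex(
            ComplexSpec(
                components=[lys, glu],
                placements=[RigidTransform.identity(), RigidTransform.identity()],
                designed_contacts=[(("A", 21, "NZ"), ("B", 40, "OE1"), 3.0)],
            )
        )
        edges = detect_interactions(complex_model)
        assert sum(e.type == "IONIC" and e.inter_chain for e in edges) == 1

    def test_unsatisfied_contact_raises(self):
        lys = StructureModel(
            id="a", chains={"A": [contact_probe("LYS", "A", 21, (0, 0, 0), direction=(1, 0, 0))]}
        )
        glu = StructureModel(
            id="b", chains={"B": [contact_probe("GLU", "B", 40, (9.0, 0, 0), direction=(-1, 0, 0))]}
        )
        with pytest.raises(ValueError, match="designed contact"):
            make_complex(
                ComplexSpec(
                    components=[lys, glu],
                    placements=[RigidTransform.identity(), RigidTransform.identity()],
                    designed_contacts=[(("A", 21, "NZ"), ("B", 40, "OE1"), 3.0)],
                )
            )

    def test_duplicate_chain_ids_rejected(self):
        a = StructureModel(id="a", chains={"A": [contact_probe("ALA", "A", 1, (0, 0, 0))]})
        b = StructureModel(id="b", chains={"A": [contact_probe("ALA", "A", 2, (30, 0, 0))]})
        with pytest.raises(ValueError, match="chain id"):
            make_complex(ComplexSpec(components=[a, b], placements=[RigidTransform.identity()] * 2))


def make_edge(chain_a, num_a, chain_b, num_b, etype="HBOND", energy=10.0):
    return InteractionEdge(
        residue_a=(chain_a, num_a, ""),
        residue_b=(chain_b, num_b, ""),
        type=etype,
        distance=3.0,
        energy=energy,
    )


class TestInterproteinSummary:
    def test_empty_edge_list(self):
        s = interprotein_summary([])
        assert (s.n_total, s.e_total, s.n_roi, s.e_roi) == (0, 0.0, 0, 0.0)
        assert s.pct_n_roi == 0.0 and s.pct_e_roi == 0.0

    def test_quarter_roi(self):
        edges = [
            make_edge("A", 21, "B", 50),
            make_edge("A", 51, "B", 52),
            make_edge("A", 53, "B", 54),
            make_edge("A", 55, "B", 56),
        ]
        s = interprotein_summary(edges, ResiduesOfInterest())
        assert s.n_total == 4 and s.n_roi == 1
        assert s.pct_n_roi == 25.0
        assert s.e_roi == pytest.approx(10.0)
        assert s.pct_e_roi == 25.0

    def test_intra_chain_edges_ignored(self):
        edges = [make_edge("A", 21, "A", 50), make_edge("A", 21, "B", 50)]
        s = interprotein_summary(edges)
        assert s.n_total == 1

    def test_both_endpoints_rule(self):
        edges = [make_edge("A", 21, "B", 50), make_edge("A", 21, "B", 112)]
        either = interprotein_summary(edges, ResiduesOfInterest(match_rule="either_endpoint"))
        both = interprotein_summary(edges, ResiduesOfInterest(match_rule="both_endpoints"))
        assert either.n_roi == 2
        assert both.n_roi == 1

    def test_chain_relabeling_invariance(self):
        edges = [make_edge("A", 21, "B", 50), make_edge("A", 7, "B", 8, "IONIC", 20.0)]
        swapped = [
            make_edge("B", 50, "A", 21),
            make_edge("B", 8, "A", 7, "IONIC", 20.0),
        ]
        relabeled = [
            make_edge("X", 21, "Y", 50),
            make_edge("X", 7, "Y", 8, "IONIC", 20.0),
        ]
        base = interprotein_summary(edges)
        for alt in (swapped, relabeled):
            other = interprotein_summary(alt)
            assert (other.n_total, other.e_total, other.n_roi, other.e_roi) == (
                base.n_total,
                base.e_total,
                base.n_roi,
                base.e_roi,
            )

    def test_per_type_breakdown_adds_up(self):
        edges = [
            make_edge("A", 1, "B", 2, "HBOND", 17.0),
            make_edge("A", 3, "B", 4, "HBOND", 17.0),
            make_edge("A", 5, "B", 6, "IONIC", 20.0),
        ]
        s = interprotein_summary(edges)
        assert sum(c for c, _ in s.per_type_breakdown.values()) == s.n_total
        assert sum(e for _, e in s.per_type_breakdown.values()) == pytest.approx(s.e_total)


class TestSummarizeReportRow:
    @pytest.mark.parametrize(
        "n_total,e_total,n_roi,e_roi,pct_n,pct_e",
        [
            (89, 824.8, 2, 12.0, 2.2, 1.5),
            (133, 1392.8, 74, 817.0, 55.6, 58.7),
            (100, 1019.0, 36, 398.0, 36.0, 39.1),
            (10, 100.0, 0, 0.0, 0.0, 0.0),
        ],
    )
    def test_row_arithmetic(self, n_total, e_total, n_roi, e_roi, pct_n, pct_e):
        row = summarize_report_row(n_total, e_total, n_roi, e_roi)
        assert row["pct_n_roi"] == pct_n
        assert row["pct_e_roi"] == pct_e

    def test_reproduces_all_published_interface_rows(self):
        for role, rows in INTERFACE_TOTALS.items():
            for name, (n_total, n_roi, e_total, e_roi, pct_n, pct_e) in rows.items():
                row = summarize_report_row(n_total, e_total, n_roi, e_roi)
                assert row["pct_n_roi"] == pct_n, (role, name)
                assert row["pct_e_roi"] == pct_e, (role, name)

    def test_roi_exceeding_total_is_error(self):
        with pytest.raises(ValueError):
            summarize_report_row(5, 50.0, 6, 10.0)

    @given(
        st.integers(0, 500),
        st.integers(0, 500),
        st.floats(0, 5000),
        st.floats(0, 5000),
    )
    @settings(max_examples=60, deadline=None)
    def test_percent_bounds(self, n_roi, extra_n, e_roi, extra_e):
        row = summarize_report_row(n_roi + extra_n, e_roi + extra_e, n_roi, e_roi)
        assert 0.0 <= row["pct_n_roi"] <= 100.0
        assert 0.0 <= row["pct_e_roi"] <= 100.0
        if extra_n == 0 and row["n_total"] > 0:
            assert row["pct_n_roi"] == 100.0


def test_edge_uniqueness_brute_force():
    """No duplicate (pair, type) edges on a crowded synthetic interface."""
    chain_a = [contact_probe("LYS", "A", i, (0, 4.0 * i, 0), direction=(1, 0, 0)) for i in range(1, 4)]
    chain_b = [
        contact_probe("GLU", "B", 10 + i, (3.0, 4.0 * i, 0), direction=(-1, 0, 0))
        for i in range(1, 4)
    ]
    m = StructureModel(id="grid", chains={"A": chain_a, "B": chain_b})
    edges = detect_interactions(m)
    keys = [(tuple(sorted((e.residue_a, e.residue_b))), e.type) for e in edges]
    assert len(keys) == len(set(keys))
    for e in edges:
        assert e.distance <= 7.0
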