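"""Study orchestration: monomer comparison, cluster analysis, interfaces.

``run_study`` chains the modules end to end: superposition and the
shared-displacement filter on reference vs. variants, contact-network
construction and MCODE clustering per structure with a cross-structure
cluster comparison, the cluster-score/B-factor correlation, and — when
complexes are given — interprotein interaction summaries.  The derived
residues of interest are the union of the shared displaced residues and the
consistently changed cluster residues, unless an explicit set overrides
them.  Outputs are deterministic for identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rincompare import __version__
from rincompare.bfactor_stats import (
    ClusterBFactor,
    CorrelationResult,
    average_cluster_bfactor,
    score_bfactor_correlation,
)
from rincompare.interface_energetics import (
    InteractionConfig,
    InterfaceSummary,
    ResiduesOfInterest,
    detect_interactions,
    interprotein_summary,
)
from rincompare.rin_mcode import (
    ClusterComparison,
    ContactNetwork,
    MCODECluster,
    MCODEParams,
    build_contact_network,
    compare_clusters,
    mcode_find_clusters,
)
from rincompare.structure_io import StructureModel, read_pdb
from rincompare.superpose import (
    DisplacementConfig,
    DisplacementReport,
    per_residue_rmsd,
    shared_displaced_residues,
)

__all__ = ["RunConfig", "StudyReport", "run_study", "emit_reports"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a study run; defaults are the lysozyme-study settings."""

    reference_path: Optional[str] = None
    variant_paths: List[str] = field(default_factory=list)
    complex_paths: List[Tuple[str, str]] = field(default_factory=list)  # (role, path)
    displacement: DisplacementConfig = field(default_factory=DisplacementConfig)
    contact_cutoff: float = 7.0
    mcode: MCODEParams = field(default_factory=MCODEParams)
    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    roi: Optional[ResiduesOfInterest] = None  # None -> derived from the analysis
    top_clusters_for_correlation: int = 4
    significance_threshold: float = 0.05
    output_dir: Optional[str] = None

    def echo(self) -> dict:
        """Every threshold used, for the report's config echo."""
        return {
            "version": __version__,
            "rmsd_threshold": self.displacement.rmsd_threshold,
            "atom_scope": self.displacement.atom_scope,
            "iterative_fit": self.displacement.iterative_fit,
            "contact_cutoff": self.contact_cutoff,
            "mcode": {
                "degree_cutoff": self.mcode.degree_cutoff,
                "node_score_cutoff": self.mcode.node_score_cutoff,
                "k_core_filter": self.mcode.k_core_filter,
                "max_depth": self.mcode.max_depth,
                "haircut": self.mcode.haircut,
                "fluff": self.mcode.fluff,
                "min_cluster_score": self.mcode.min_cluster_score,
            },
            "interaction_thresholds": dict(self.interactions.thresholds),
            "interaction_energies": dict(self.interactions.energies),
            "min_sequence_separation": self.interactions.min_sequence_separation,
            "roi": sorted(self.roi.residues) if self.roi else None,
            "roi_match_rule": self.roi.match_rule if self.roi else "either_endpoint",
            "top_clusters_for_correlation": self.top_clusters_for_correlation,
            "significance_threshold": self.significance_threshold,
        }


@dataclass
class StudyReport:
    """All study outputs; sections are None when the inputs were not given."""

    config_echo: dict
    displacement_reports: Dict[str, DisplacementReport] = field(default_factory=dict)
    shared_displaced: Set = field(default_factory=set)
    networks: Dict[str, ContactNetwork] = field(default_factory=dict)
    clusters: Dict[str, List[MCODECluster]] = field(default_factory=dict)
    cluster_comparison: Optional[ClusterComparison] = None
    cluster_bfactors: Dict[str, List[ClusterBFactor]] = field(default_factory=dict)
    correlation: Optional[CorrelationResult] = None
    derived_roi: Set[int] = field(default_factory=set)
    interfaces: Dict[str, InterfaceSummary] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"config": self.config_echo}
        out["displacement"] = {
            vid: {
                "fit_rmsd": rep.fit_rmsd,
                "per_residue_rmsd": {
                    "|".join(map(str, k)): v for k, v in sorted(rep.per_residue_rmsd.items())
                },
            }
            for vid, rep in sorted(self.displacement_reports.items())
        }
        out["shared_displaced_residues"] = sorted(k[1] for k in self.shared_displaced)
        out["clusters"] = {
            sid: [
                {
                    "rank": c.rank,
                    "score": c.score,
                    "members": c.residue_numbers(self.networks[sid]),
                }
                for c in cl
            ]
            for sid, cl in sorted(self.clusters.items())
        }
        if self.cluster_comparison is not None:
            out["cluster_comparison"] = {
                "reference": self.cluster_comparison.reference_id,
                "consistent_changes": sorted(self.cluster_comparison.consistent_changes),
                "matches": [
                    {
                        "structure": m.structure_id,
                        "variant_rank": m.variant_rank,
                        "reference_rank": m.reference_rank,
                        "jaccard": m.jaccard,
                        "gained": sorted(m.gained),
                        "lost": sorted(m.lost),
                        "score_delta": m.score_delta,
                    }
                    for m in self.cluster_comparison.matches
                ],
            }
        out["cluster_bfactors"] = {
            sid: [
                {"rank": b.cluster_rank, "avg_b": b.avg_b, "n_residues": b.n_residues}
                for b in rows
            ]
            for sid, rows in sorted(self.cluster_bfactors.items())
        }
        if self.correlation is not None:
            out["correlation"] = {
                "r": self.correlation.r,
                "r_squared": self.correlation.r_squared,
                "p_two_sided": self.correlation.p_two_sided,
                "n": self.correlation.n,
                "significant": self.correlation.significant,
            }
        out["derived_residues_of_interest"] = sorted(self.derived_roi)
        out["interfaces"] = {
            name: {
                "n_total": s.n_total,
                "e_total": s.e_total,
                "n_roi": s.n_roi,
                "e_roi": s.e_roi,
                "pct_n_roi": s.pct_n_roi,
                "pct_e_roi": s.pct_e_roi,
                "per_type": {t: list(v) for t, v in s.per_type_breakdown.items()},
            }
            for name, s in sorted(self.interfaces.items())
        }
        return out


def _load(path_or_model, model_id=None) -> StructureModel:
    if isinstance(path_or_model, StructureModel):
        return path_or_model
    return read_pdb(str(path_or_model), model_id=model_id)


def run_study(
    config: RunConfig,
    *,
    reference: Optional[StructureModel] = None,
    variants: Optional[Sequence[StructureModel]] = None,
    complexes: Optional[Dict[str, StructureModel]] = None,
) -> StudyReport:
    """Execute the full comparison.  Structures may be passed in memory
    (``reference``/``variants``/``complexes``) or read from the paths in
    *config*; in-memory inputs win."""
    if reference is None:
        if config.reference_path is None:
            raise ValueError("no reference structure given")
        reference = _load(config.reference_path)
    if variants is None:
        variants = [_load(p) for p in config.variant_paths]
    if complexes is None:
        complexes = {
            f"{role}:{Path(p).stem}": _load(p) for role, p in config.complex_paths
        }
    if not variants:
        raise ValueError("need at least one variant for a comparison run")

    report = StudyReport(config_echo=config.echo())

    # 1. superposition + shared-displacement filter
    for var in variants:
        try:
            rep = per_residue_rmsd(reference, var, config.displacement)
        except Exception as exc:
            raise RuntimeError(f"superposition failed for {var.id!r}: {exc}") from exc
        report.displacement_reports[var.id] = rep
    report.shared_displaced = shared_displaced_residues(
        report.displacement_reports.values(), config.displacement
    )

    # 2. contact networks + MCODE clusters
    for model in [reference, *variants]:
        try:
            net = build_contact_network(model, cutoff=config.contact_cutoff)
            report.networks[model.id] = net
            report.clusters[model.id] = mcode_find_clusters(net, config.mcode)
        except Exception as exc:
            raise RuntimeError(f"network/cluster stage failed for {model.id!r}: {exc}") from exc
    report.cluster_comparison = compare_clusters(
        report.clusters, report.networks, reference_id=reference.id
    )

    # 3. cluster-average B-factors + correlation over top clusters
    pairs = []
    by_id = {m.id: m for m in [reference, *variants]}
    for sid, cluster_list in report.clusters.items():
        rows = []
        for c in cluster_list:
            keys = [
                report.networks[sid].graph.nodes[v]["residue_key"] for v in c.members
            ]
            rows.append(average_cluster_bfactor(by_id[sid], keys, cluster_rank=c.rank))
        report.cluster_bfactors[sid] = rows
        for c, b in zip(cluster_list, rows):
            if c.rank <= config.top_clusters_for_correlation:
                pairs.append((c.score, b.avg_b))
    if len(pairs) >= 3:
        try:
            report.correlation = score_bfactor_correlation(
                pairs, config.significance_threshold
            )
        except ValueError as exc:
            logger.warning("correlation not computed: %s", exc)

    # 4. derived residues of interest
    report.derived_roi = {k[1] for k in report.shared_displaced} | set(
        report.cluster_comparison.consistent_changes
    )
    roi = config.roi
    if roi is None and report.derived_roi:
        roi = ResiduesOfInterest(residues=set(report.derived_roi))

    # 5. interfaces
    for name, model in complexes.items():
        try:
            edges = detect_interactions(model, config.interactions)
            report.interfaces[name] = interprotein_summary(
                edges, roi or ResiduesOfInterest()
            )
        except Exception as exc:
            raise RuntimeError(f"interface stage failed for {name!r}: {exc}") from exc

    return report


def emit_reports(report: StudyReport, outdir: str) -> List[str]:
    """Write the machine-readable JSON plus TSV tables; returns paths.

    The cluster TSV is ordered by (structure, rank); interface TSV rows
    carry the same one-decimal percentages as the summary objects.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    jpath = out / "study_report.json"
    jpath.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    written.append(str(jpath))

    lines = ["structure\trank\tscore\tmembers\tavg_b_factor"]
    for sid in sorted(report.clusters):
        bmap = {b.cluster_rank: b.avg_b for b in report.cluster_bfactors.get(sid, [])}
        for c in sorted(report.clusters[sid], key=lambda c: c.rank):
            members = ",".join(map(str, c.residue_numbers(report.networks[sid])))
            avg_b = bmap.get(c.rank)
            lines.append(
                f"{sid}\t{c.rank}\t{c.score:.2f}\t{members}\t"
                f"{'' if avg_b is None else f'{avg_b:.2f}'}"
            )
    cpath = out / "clusters.tsv"
    cpath.write_text("\n".join(lines) + "\n")
    written.append(str(cpath))

    if report.interfaces:
        lines = [
            "complex\tn_total\tn_roi\tpct_n_roi\te_total_kJ_mol\te_roi_kJ_mol\tpct_e_roi"
        ]
        for name in sorted(report.interfaces):
            s = report.interfaces[name]
            lines.append(
                f"{name}\t{s.n_total}\t{s.n_roi}\t{s.pct_n_roi}\t"
                f"{s.e_total:.1f}\t{s.e_roi:.1f}\t{s.pct_e_roi}"
            )
        ipath = out / "interfaces.tsv"
        ipath.write_text("\n".join(lines) + "\n")
        written.append(str(ipath))

    lpath = out / "run_log.txt"
    lpath.write_text(
        json.dumps({"config": report.config_echo}, indent=2, sort_keys=True) + "\n"
    )
    written.append(str(lpath))
    return written
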