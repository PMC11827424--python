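"""End-to-end orchestration: phenotype → detect → merge → qualify →
metrics → statistics, over one or many sections.

The pipeline is deterministic given its inputs and parameters; writing
outputs twice from the same inputs produces byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .clustering import ClusteringParams, detect_aggregates, merge_connected
from .io import SectionDataset, write_outputs
from .metrics import SectionSummary, section_areas, section_table, summarize_section
from .phenotyping import UNDEFINED, phenotype_cells
from .qualification import (
    QualificationParams,
    TLSDomain,
    domain_table,
    qualify_section,
)
from .stats import (
    compare_rankings,
    correlation_table,
    ki67_correlation_suite,
    rank_patients,
    ranking_table,
    treg_presence_analysis,
)

logger = logging.getLogger("tlsquant")


@dataclass
class RunConfig:
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    qualification: QualificationParams = field(default_factory=QualificationParams)
    corr_min_cells: int = 50
    rank_top_k: int = 8
    tissue_grid_um: float = 50.0
    region_tolerance_um: float = 1.0
    seed: int | None = None

    def manifest_params(self) -> dict:
        return {
            "clustering": {
                "neighbour_radius_um": self.clustering.neighbour_radius_um,
                "min_neighbours": self.clustering.min_neighbours,
                "strand_link_radius_um": self.clustering.strand_link_radius_um,
                "strand_min_path_cells": self.clustering.strand_min_path_cells,
                "hull_alpha_um": self.clustering.hull_alpha_um,
            },
            "qualification": {
                "min_cells": self.qualification.min_cells,
                "min_lymph_frac": self.qualification.min_lymph_frac,
            },
            "corr_min_cells": self.corr_min_cells,
            "rank_top_k": self.rank_top_k,
            "tissue_grid_um": self.tissue_grid_um,
            "coordinate_convention": "µm, origin top-left, y increasing downward",
            "gate_order": "CD3+CD8+ -> CD8T; CD3+Foxp3+ -> CD4Treg; CD3+ -> CD4Tconv; CD20+CD3- -> B; else undefined",
            "seed": self.seed,
        }


@dataclass
class SectionResult:
    dataset: SectionDataset
    labelled: pd.DataFrame
    domains: list[TLSDomain]
    rejections: list
    summary: SectionSummary
    stage_counts: dict


@dataclass
class PipelineResult:
    sections: list[SectionResult]
    domain_table: pd.DataFrame
    section_table: pd.DataFrame
    correlation_table: pd.DataFrame
    ranking_table: pd.DataFrame
    concordance: dict
    manifest: dict

    @property
    def all_domains(self) -> list[TLSDomain]:
        return [d for s in self.sections for d in s.domains]

    @property
    def summaries(self) -> list[SectionSummary]:
        return [s.summary for s in self.sections]


def process_section(dataset: SectionDataset, config: RunConfig) -> SectionResult:
    """Run the per-section stages on one loaded dataset."""
    dataset.validate_regions(config.region_tolerance_um)
    labelled = phenotype_cells(dataset.cells)
    lymphocytes = labelled.loc[labelled["subset"] != UNDEFINED, ["cell_id", "x", "y"]]
    clusters = detect_aggregates(lymphocytes, config.clustering)
    merged = merge_connected(clusters, lymphocytes, config.clustering)
    domains, rejections = qualify_section(
        merged, labelled, config.qualification, section_id=dataset.section_id
    )
    areas = section_areas(
        domains,
        dataset.tissue_regions,
        dataset.tumour_regions,
        cells=dataset.cells,
        grid_um=config.tissue_grid_um,
    )
    summary = summarize_section(dataset.section_id, dataset.patient_id, domains, areas)
    stage_counts = {
        "n_cells": int(len(dataset.cells)),
        "n_dropped_rows": dataset.n_dropped_rows,
        "n_lymphocytes": int(len(lymphocytes)),
        "n_aggregates_detected": len(clusters),
        "n_aggregates_after_merge": len(merged),
        "n_qualified": len(domains),
        "n_rejected": len(rejections),
        "rejections_by_reason": {
            reason: sum(1 for r in rejections if r.reason == reason)
            for reason in sorted({r.reason for r in rejections})
        },
    }
    logger.info(
        "section %s: %d cells, %d lymphocytes, %d aggregates (%d after merge), "
        "%d qualified, %d rejected",
        dataset.section_id,
        stage_counts["n_cells"],
        stage_counts["n_lymphocytes"],
        stage_counts["n_aggregates_detected"],
        stage_counts["n_aggregates_after_merge"],
        stage_counts["n_qualified"],
        stage_counts["n_rejected"],
    )
    return SectionResult(dataset, labelled, domains, rejections, summary, stage_counts)


def run_pipeline(
    sections: list[SectionDataset],
    config: RunConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run all stages over a list of sections and assemble the outputs.

    When ``out_dir`` is given, tables and the manifest are written there
    via :func:`tlsquant.io.write_outputs`.
    """
    config = config or RunConfig()
    section_results = [process_section(ds, config) for ds in sections]

    patient_ids = {ds.section_id: ds.patient_id for ds in sections}
    all_domains = [d for s in section_results for d in s.domains]
    all_rejections = [r for s in section_results for r in s.rejections]
    summaries = [s.summary for s in section_results]

    correlations = ki67_correlation_suite(
        domains=all_domains, level="domain", min_cells=config.corr_min_cells
    )
    correlations += ki67_correlation_suite(summaries=summaries, level="section")
    correlations += treg_presence_analysis(all_domains, min_cells=config.corr_min_cells)

    ranking_canonical = rank_patients(summaries, "per_domain_mean")
    ranking_pooled = rank_patients(summaries, "pooled")
    concordance = compare_rankings(ranking_canonical, ranking_pooled, k=config.rank_top_k)

    manifest = {
        "tool": "tlsquant",
        "version": __version__,
        "parameters": config.manifest_params(),
        "sections": {s.dataset.section_id: s.stage_counts for s in section_results},
        "n_sections": len(section_results),
        "n_domains_total": len(all_domains),
        "concordance": concordance,
        "notes": [
            "coordinate units assumed µm unless unit_scale given at load time",
            "per-domain correlation p-values assume independent domains "
            "(within-patient clustering not modelled)",
        ],
    }

    result = PipelineResult(
        sections=section_results,
        domain_table=domain_table(all_domains, all_rejections, patient_ids),
        section_table=section_table(summaries),
        correlation_table=correlation_table(correlations),
        ranking_table=ranking_table([ranking_canonical, ranking_pooled]),
        concordance=concordance,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result
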