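"""Per-domain and whole-section quantities.

Two complementary readouts of TLS activity are computed from qualified
domains:

* the canonical per-domain route — each domain's composition fractions and
  Ki-67 fractions, averaged per section with one vote per domain; and
* the whole-section route — compositions of all domains in a section
  pooled (element-wise integer sum) before fractions are taken, so large
  domains weigh in proportion to their cell counts.

Areas are measured on the polygon geometry: total TLS area is the area of
the union of domain boundaries (overlaps counted once), clipped to the
tissue outline when one is available; the tumour area is likewise clipped.
When no tissue annotation exists, the tissue area is estimated from the
cell point pattern by grid occupancy (a tile counts as tissue if it holds
at least one cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .phenotyping import LYMPHOCYTE_LABELS, SUBSETS
from .qualification import DomainComposition, TLSDomain

#: minimum number of cells for grid-occupancy tissue estimation
MIN_CELLS_FOR_TISSUE_ESTIMATE = 100


@dataclass
class SectionAreas:
    total_tls_area: float
    tissue_area: float  # nan when not measurable
    tumour_area: float
    tissue_estimated: bool = False


@dataclass
class SectionSummary:
    """Whole-section rollup over qualified TLS domains."""

    section_id: str
    patient_id: str
    n_domains: int
    total_tls_area: float
    tissue_area: float
    tumour_area: float
    tls_area_fraction: float
    tumour_area_fraction: float
    pooled: DomainComposition
    mean_per_domain_ki67: dict[str, float] = field(default_factory=dict)


def ki67_fraction(composition: DomainComposition, subset: str) -> float:
    """Fraction of a lymphocyte subset that is Ki-67+.

    NaN sentinel when the subset is absent from the composition.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown lymphocyte subset {subset!r}")
    denom = composition.subset_count(subset)
    if denom == 0:
        return float("nan")
    return composition.ki67_pos_count(subset) / denom


def composition_fractions(composition: DomainComposition) -> dict[str, float]:
    """Each of the 8 lymphocyte classes as a fraction of all lymphocytes.

    Undefined cells are excluded from the denominator; the 8 fractions sum
    to 1.  All-NaN when the composition holds no lymphocytes.
    """
    n = composition.n_lymph
    if n == 0:
        return {lab: float("nan") for lab in LYMPHOCYTE_LABELS}
    return {lab: composition.counts[lab] / n for lab in LYMPHOCYTE_LABELS}


def pool_section(domains: list[TLSDomain]) -> DomainComposition:
    """Element-wise integer sum of the domains' compositions."""
    pooled = DomainComposition.zero()
    for d in domains:
        pooled = pooled + d.composition
    return pooled


def estimate_tissue_area_from_cells(
    cells: pd.DataFrame, grid_um: float = 50.0
) -> float:
    """Grid-occupancy tissue area: occupied tiles × tile area (µm²)."""
    if len(cells) == 0:
        return float("nan")
    ix = np.floor(cells["x"].to_numpy(dtype=float) / grid_um).astype(np.int64)
    iy = np.floor(cells["y"].to_numpy(dtype=float) / grid_um).astype(np.int64)
    n_tiles = len(np.unique(ix * (iy.max() - iy.min() + 2) + iy))
    return float(n_tiles) * grid_um * grid_um


def section_areas(
    domains: list[TLSDomain],
    tissue_regions=None,
    tumour_regions=None,
    cells: pd.DataFrame | None = None,
    grid_um: float = 50.0,
) -> SectionAreas:
    """Total TLS, tissue and tumour areas for one section (µm²).

    Domain polygons are unioned (overlaps counted once).  With tissue
    polygons, TLS and tumour geometry are clipped to the tissue union so
    area fractions are ≤ 1 by construction.  Without tissue polygons the
    tissue area is estimated from the cells by grid occupancy; if there
    are too few cells for that, the tissue area is NaN and fractions are
    undefined.
    """
    tls_geoms = [
        d.cluster.boundary
        for d in domains
        if d.cluster is not None and not d.cluster.degenerate
    ]
    tls_union = unary_union(tls_geoms) if tls_geoms else None

    tumour_union = unary_union(list(tumour_regions)) if tumour_regions else None

    if tissue_regions:
        tissue = unary_union(list(tissue_regions))
        tissue_area = float(tissue.area)
        tls_area = float(tls_union.intersection(tissue).area) if tls_union is not None else 0.0
        tumour_area = (
            float(tumour_union.intersection(tissue).area) if tumour_union is not None else 0.0
        )
        return SectionAreas(tls_area, tissue_area, tumour_area, tissue_estimated=False)

    tls_area = float(tls_union.area) if tls_union is not None else 0.0
    tumour_area = float(tumour_union.area) if tumour_union is not None else 0.0
    if cells is not None and len(cells) >= MIN_CELLS_FOR_TISSUE_ESTIMATE:
        tissue_area = estimate_tissue_area_from_cells(cells, grid_um)
        return SectionAreas(tls_area, tissue_area, tumour_area, tissue_estimated=True)
    return SectionAreas(tls_area, float("nan"), tumour_area, tissue_estimated=False)


def mean_per_domain_ki67(domains: list[TLSDomain]) -> dict[str, float]:
    """Unweighted mean over domains of each subset's Ki-67 fraction.

    Each domain gets one vote; domains where a subset is absent are left
    out of that subset's mean (NaN when no domain has the subset).
    """
    out: dict[str, float] = {}
    for subset in SUBSETS:
        vals = [ki67_fraction(d.composition, subset) for d in domains]
        vals = [v for v in vals if not math.isnan(v)]
        out[subset] = float(np.mean(vals)) if vals else float("nan")
    return out


def summarize_section(
    section_id: str,
    patient_id: str,
    domains: list[TLSDomain],
    areas: SectionAreas,
) -> SectionSummary:
    """Assemble the whole-section rollup."""
    pooled = pool_section(domains)
    tissue = areas.tissue_area
    tls_frac = areas.total_tls_area / tissue if tissue and not math.isnan(tissue) else float("nan")
    tum_frac = areas.tumour_area / tissue if tissue and not math.isnan(tissue) else float("nan")
    return SectionSummary(
        section_id=section_id,
        patient_id=patient_id,
        n_domains=len(domains),
        total_tls_area=areas.total_tls_area,
        tissue_area=tissue,
        tumour_area=areas.tumour_area,
        tls_area_fraction=tls_frac,
        tumour_area_fraction=tum_frac,
        pooled=pooled,
        mean_per_domain_ki67=mean_per_domain_ki67(domains),
    )


def section_table(summaries: list[SectionSummary]) -> pd.DataFrame:
    """Tabulate section summaries for output."""
    rows = []
    for s in summaries:
        row = {
            "section_id": s.section_id,
            "patient_id": s.patient_id,
            "n_domains": s.n_domains,
            "total_tls_area_um2": s.total_tls_area,
            "tissue_area_um2": s.tissue_area,
            "tumour_area_um2": s.tumour_area,
            "tls_area_fraction": s.tls_area_fraction,
            "tumour_area_fraction": s.tumour_area_fraction,
        }
        for lab, count in s.pooled.counts.items():
            row[f"pooled_{lab}"] = count
        for subset in SUBSETS:
            row[f"pooled_ki67_frac_{subset}"] = ki67_fraction(s.pooled, subset)
            row[f"mean_per_domain_ki67_{subset}"] = s.mean_per_domain_ki67.get(
                subset, float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
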