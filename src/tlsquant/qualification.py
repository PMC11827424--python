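"""TLS inclusion criteria: which aggregates count as TLS domains.

An aggregate qualifies as a TLS domain when it holds at least
``min_cells`` cells in total (every cell inside its boundary, lymphocyte
or undefined) of which strictly more than ``min_lymph_frac`` are
lymphocytes (B and/or T cells).  Defaults are 250 cells and 0.5 — size is
an inclusive bound, the fraction strictly exclusive.

Composition counts every cell whose centroid falls inside or on the
aggregate boundary, not only the clustered lymphocytes, because the
denominator of the lymphocyte fraction is all cells in the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from .phenotyping import ALL_LABELS, LYMPHOCYTE_LABELS, UNDEFINED
from .clustering import AggregateCluster

REJECT_SIZE = "too_few_cells"
REJECT_LYMPH_FRACTION = "lymphocyte_fraction_too_low"


@dataclass(frozen=True)
class QualificationParams:
    min_cells: int = 250
    min_lymph_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.min_cells <= 0 or not (0 <= self.min_lymph_frac < 1):
            raise ValueError("invalid qualification thresholds")


@dataclass(frozen=True)
class DomainComposition:
    """Counts of the nine phenotype classes within one aggregate."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {lab: int(self.counts.get(lab, 0)) for lab in ALL_LABELS}
        )
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative phenotype count")

    @classmethod
    def zero(cls) -> "DomainComposition":
        return cls({})

    @property
    def n_lymph(self) -> int:
        return sum(self.counts[lab] for lab in LYMPHOCYTE_LABELS)

    @property
    def n_total(self) -> int:
        return self.n_lymph + self.counts[UNDEFINED]

    @property
    def lymph_fraction(self) -> float:
        return self.n_lymph / self.n_total if self.n_total else float("nan")

    def subset_count(self, subset: str) -> int:
        return self.counts[f"{subset}_Ki67pos"] + self.counts[f"{subset}_Ki67neg"]

    def ki67_pos_count(self, subset: str) -> int:
        return self.counts[f"{subset}_Ki67pos"]

    def __add__(self, other: "DomainComposition") -> "DomainComposition":
        return DomainComposition(
            {lab: self.counts[lab] + other.counts[lab] for lab in ALL_LABELS}
        )


@dataclass
class TLSDomain:
    """A qualified aggregate with its composition and area."""

    domain_id: str
    section_id: str
    composition: DomainComposition
    area_um2: float
    cluster: AggregateCluster | None = None


@dataclass
class Rejection:
    """An aggregate that failed the inclusion criteria."""

    section_id: str
    composition: DomainComposition
    reason: str
    cluster: AggregateCluster | None = None


def compose(
    cluster: AggregateCluster, labelled_cells: pd.DataFrame
) -> DomainComposition:
    """Phenotype composition of every cell inside the cluster boundary.

    ``labelled_cells`` is the full labelled cell table for the section
    (all cells, including undefined ones).  Membership is point-in-polygon
    on cell centroids, boundary inclusive.  A degenerate (zero-area)
    boundary yields the all-zero composition.
    """
    if cluster.degenerate or cluster.boundary.is_empty:
        return DomainComposition.zero()
    x = labelled_cells["x"].to_numpy(dtype=float)
    y = labelled_cells["y"].to_numpy(dtype=float)
    minx, miny, maxx, maxy = cluster.boundary.bounds
    near = np.flatnonzero((x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy))
    inside = near[shapely.intersects_xy(cluster.boundary, x[near], y[near])]
    vc = labelled_cells["label"].iloc[inside].value_counts()
    return DomainComposition({lab: int(vc.get(lab, 0)) for lab in ALL_LABELS})


def qualify(
    cluster: AggregateCluster,
    composition: DomainComposition,
    params: QualificationParams | None = None,
    *,
    domain_id: str = "d0001",
    section_id: str = "section",
) -> TLSDomain | Rejection:
    """Apply the inclusion criteria to one composed aggregate.

    Accepted iff ``n_total >= min_cells`` and
    ``n_lymph / n_total > min_lymph_frac`` (strict).  Rejections carry a
    machine-readable reason (:data:`REJECT_SIZE` or
    :data:`REJECT_LYMPH_FRACTION`); the size criterion is checked first.
    """
    params = params or QualificationParams()
    if composition.n_total < params.min_cells:
        return Rejection(section_id, composition, REJECT_SIZE, cluster)
    if not composition.n_lymph > params.min_lymph_frac * composition.n_total:
        return Rejection(section_id, composition, REJECT_LYMPH_FRACTION, cluster)
    return TLSDomain(domain_id, section_id, composition, cluster.area_um2, cluster)


def qualify_section(
    clusters: list[AggregateCluster],
    labelled_cells: pd.DataFrame,
    params: QualificationParams | None = None,
    *,
    section_id: str = "section",
) -> tuple[list[TLSDomain], list[Rejection]]:
    """Compose and qualify every cluster of a section."""
    params = params or QualificationParams()
    domains: list[TLSDomain] = []
    rejections: list[Rejection] = []
    for idx, cluster in enumerate(clusters):
        comp = compose(cluster, labelled_cells)
        result = qualify(
            cluster,
            comp,
            params,
            domain_id=f"{section_id}_d{idx + 1:04d}",
            section_id=section_id,
        )
        if isinstance(result, TLSDomain):
            domains.append(result)
        else:
            rejections.append(result)
    return domains, rejections


def domain_table(
    domains: list[TLSDomain],
    rejections: list[Rejection] | None = None,
    patient_ids: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate qualified domains (and optionally rejections) for output."""
    rows = []
    for d in domains:
        rows.append(_domain_row(d.domain_id, d.section_id, d.composition, d.area_um2, True, "", d.cluster, patient_ids))
    for i, r in enumerate(rejections or []):
        area = r.cluster.area_um2 if r.cluster is not None else np.nan
        rows.append(_domain_row(f"{r.section_id}_r{i + 1:04d}", r.section_id, r.composition, area, False, r.reason, r.cluster, patient_ids))
    columns = (
        ["domain_id", "section_id", "patient_id", "n_total", "n_lymph"]
        + list(ALL_LABELS)
        + ["area_um2", "centroid_x", "centroid_y", "qualified", "rejection_reason"]
    )
    return pd.DataFrame(rows, columns=columns)


def _domain_row(domain_id, section_id, comp, area, qualified, reason, cluster, patient_ids):
    row = {
        "domain_id": domain_id,
        "section_id": section_id,
        "patient_id": (patient_ids or {}).get(section_id, ""),
        "n_total": comp.n_total,
        "n_lymph": comp.n_lymph,
        **comp.counts,
        "area_um2": area,
        "centroid_x": cluster.centroid[0] if cluster is not None else np.nan,
        "centroid_y": cluster.centroid[1] if cluster is not None else np.nan,
        "qualified": qualified,
        "rejection_reason": reason,
    }
    return row
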