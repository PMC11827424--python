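"""Synthetic tissue-section cohorts with full ground truth.

The generator emulates the data shape the pipeline consumes: per-section
cell point patterns containing ovoid and multi-lobular lymphoid
aggregates (B-cell rich cores with variable T-cell content), optional
germinal-centre-like Ki-67+ B hotspots, thin lymphocyte strands bridging
lobes of one structure, scattered background lymphocytes, and
marker-negative (undefined) cells everywhere.

Statistical structure:

* each planted domain draws its subset composition from a Dirichlet;
* each patient carries a latent activation value, Normal(0, sd) on the
  logit scale, shared by all of that patient's cells — raising Ki-67
  probability in every subset simultaneously and thereby inducing the
  cross-subset proliferation correlation the analysis looks for;
* per-cell Ki-67 is Bernoulli with
  ``p = logistic(base_logit[subset] + activation
  − suppression_coeff · treg_presence)`` where ``treg_presence`` is the
  realised Foxp3+ CD4 fraction among the domain's lymphocytes
  (``suppression_coeff`` defaults to 0: no planted suppression);
* marker calls are generated from the intended labels, never the other
  way round, so the phenotype gate inverts them exactly.

Ground truth is bookkept during generation (memberships, per-domain
counts, polygons, activations) and is geometrically consistent: a
point-in-polygon recount of the emitted cells reproduces the truth counts
exactly (background cells falling inside a planted polygon are credited
to that domain; strand cells lie outside all polygons by construction).

All randomness flows from one integer seed; each section uses its own
stream keyed by (seed, section index), so cohorts are reproducible and
sections could be generated in parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .clustering import AggregateCluster
from .io import SectionDataset
from .phenotyping import ALL_LABELS, SUBSETS, UNDEFINED
from .qualification import DomainComposition, QualificationParams, TLSDomain, qualify

#: deterministic marker calls (cd20, cd3, cd8, foxp3) per intended subset
MARKER_CALLS: dict[str, tuple[bool, bool, bool, bool]] = {
    "B": (True, False, False, False),
    "CD8T": (False, True, True, False),
    "CD4Tconv": (False, True, False, False),
    "CD4Treg": (False, True, False, True),
    UNDEFINED: (False, False, False, False),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    Defaults emulate a 22-patient colorectal-cancer cohort: one whole
    section per patient (10×10 mm of tissue), 4–100 TLS domains per section,
    domain radii 80–180 µm (lymphocyte packing 0.01 cells/µm², i.e. ~10 µm
    spacing), multi-lobular morphology with occasional strand-bridged
    lobes, and a between-patient activation spread of 1.0 on the logit
    scale.  Under these settings per-section TLS area fractions land in
    the fraction-of-a-percent to several-percent range and per-domain
    B-cell Ki-67+ fractions span from ~0 to >0.9.
    """

    n_patients: int = 22
    sections_per_patient: int = 1
    domain_count_range: tuple[int, int] = (4, 100)
    domain_radius_range: tuple[float, float] = (80.0, 180.0)
    lobularity: float = 1.6  # expected lobes per domain (>= 1)
    strand_probability: float = 0.35  # chance an extra lobe is strand-bridged
    lymphocyte_density_in_domain: float = 0.01  # cells/µm²
    background_cell_density: float = 0.0005  # cells/µm² (all cell types)
    background_lymphocyte_fraction: float = 0.2
    composition_dirichlet: tuple[float, float, float, float] = (8.0, 4.0, 5.0, 2.0)
    latent_activation_sd: float = 1.0
    ki67_base_logit: dict[str, float] = field(
        default_factory=lambda: {
            "B": -1.0,
            "CD8T": -2.0,
            "CD4Tconv": -1.8,
            "CD4Treg": -1.6,
        }
    )
    suppression_coeff: float = 0.0
    undefined_fraction_in_domain: float = 0.25
    undefined_ki67_rate: float = 0.05
    gc_probability: float = 0.35
    gc_boost_logit: float = 2.5
    gc_radius_frac: float = 0.45
    strand_cell_spacing_um: float = 15.0
    strand_gap_range: tuple[float, float] = (200.0, 280.0)
    min_domain_separation_um: float = 400.0
    tissue_size_um: float = 10000.0
    tumour_area_fraction_range: tuple[float, float] = (0.05, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lymphocyte_density_in_domain <= 0 or self.background_cell_density <= 0:
            raise ValueError("densities must be positive")
        if self.domain_count_range[0] < 0 or self.domain_count_range[0] > self.domain_count_range[1]:
            raise ValueError("invalid domain_count_range")
        if self.lobularity < 1:
            raise ValueError("lobularity must be >= 1")
        for p in (
            self.strand_probability,
            self.background_lymphocyte_fraction,
            self.undefined_fraction_in_domain,
            self.gc_probability,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if 2 * self.domain_radius_range[1] >= self.tissue_size_um / 2:
            raise ValueError(
                "degenerate geometry: domain diameter approaches the section size"
            )


@dataclass
class DomainTruth:
    """Planted truth for one domain."""

    domain_id: str
    section_id: str
    polygon: shapely.Geometry
    lymph_member_ids: list[str]
    undefined_member_ids: list[str]
    counts: dict[str, int]
    ki67_prob: dict[str, float]  # realised per-subset probability (non-GC)
    has_gc: bool
    gc_disc: tuple[float, float, float] | None  # (cx, cy, r)
    n_lobes: int
    n_bridges: int


@dataclass
class SectionTruth:
    section_id: str
    patient_id: str
    activation: float
    domains: list[DomainTruth]
    strand_cell_ids: list[str]
    label_totals: dict[str, int] = field(default_factory=dict)  # whole section


@dataclass
class CohortTruth:
    config: CohortConfig
    activations: dict[str, float]
    sections: list[SectionTruth]


def _segment_distance(px, py, ax, ay, bx, by) -> float:
    """Distance from point (px, py) to segment (a, b)."""
    vx, vy = bx - ax, by - ay
    denom = vx * vx + vy * vy
    t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - ax) * vx + (py - ay) * vy) / denom))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


#: clearance kept between a strand corridor and non-bridged lobes, µm.
#: Keeps strand cells outside the domain polygon and out of reach of other
#: lobes' core cells, so the strand stays a detectable noise chain.
_STRAND_CLEARANCE_UM = 60.0


def _build_lobes(rng: np.random.Generator, config: CohortConfig):
    """Relative lobe geometry for one domain: (dx, dy, r) plus bridges.

    Bridged lobes are only accepted when their connecting corridor keeps
    clear of every other lobe; when no clear direction is found the lobe
    falls back to overlapping attachment.
    """
    r0 = rng.uniform(*config.domain_radius_range)
    lobes = [(0.0, 0.0, r0)]
    bridges = []  # (lobe index a, lobe index b, gap µm)
    corridors: list[tuple[float, float, float, float]] = []  # strand segments

    def corridor_of(a_idx: int, cx: float, cy: float, r_new: float):
        ax, ay, ar = lobes[a_idx]
        d = math.hypot(cx - ax, cy - ay)
        ux, uy = (cx - ax) / d, (cy - ay) / d
        return (ax + ar * ux, ay + ar * uy, cx - r_new * ux, cy - r_new * uy)

    def clear_of_corridors(cx: float, cy: float, r_new: float) -> bool:
        return all(
            _segment_distance(cx, cy, *seg) >= r_new + _STRAND_CLEARANCE_UM
            for seg in corridors
        )

    n_extra = rng.poisson(max(config.lobularity - 1.0, 0.0))
    for _ in range(int(n_extra)):
        anchor = int(rng.integers(len(lobes)))
        ax, ay, ar = lobes[anchor]
        r_i = r0 * rng.uniform(0.55, 0.85)
        placed = False
        if rng.random() < config.strand_probability:
            gap = rng.uniform(*config.strand_gap_range)
            dist = ar + r_i + gap
            for _attempt in range(40):
                theta = rng.uniform(0, 2 * math.pi)
                cx = ax + dist * math.cos(theta)
                cy = ay + dist * math.sin(theta)
                seg = corridor_of(anchor, cx, cy, r_i)
                ok = clear_of_corridors(cx, cy, r_i)
                for li, (ox, oy, orr) in enumerate(lobes):
                    if not ok:
                        break
                    if li == anchor:
                        continue
                    # new lobe keeps a real gap to all other lobes, and the
                    # corridor segment stays clear of them
                    if math.hypot(cx - ox, cy - oy) < r_i + orr + _STRAND_CLEARANCE_UM:
                        ok = False
                    elif _segment_distance(ox, oy, *seg) < orr + _STRAND_CLEARANCE_UM:
                        ok = False
                if ok:
                    bridges.append((anchor, len(lobes), gap))
                    lobes.append((cx, cy, r_i))
                    corridors.append(seg)
                    placed = True
                    break
        if not placed:
            for _attempt in range(40):
                theta = rng.uniform(0, 2 * math.pi)
                dist = (ar + r_i) * rng.uniform(0.6, 0.9)
                cx = ax + dist * math.cos(theta)
                cy = ay + dist * math.sin(theta)
                # overlapping lobes must not encroach on existing corridors
                if clear_of_corridors(cx, cy, r_i):
                    lobes.append((cx, cy, r_i))
                    break
    return lobes, bridges


def _sample_in_polygon(rng: np.random.Generator, polygon, n: int) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = polygon.bounds
    out = []
    got = 0
    while got < n:
        m = max(int((n - got) * 2.5), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.intersects_xy(polygon, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts)
        got += len(pts)
    return np.concatenate(out)[:n]


def _place_domains(rng: np.random.Generator, config: CohortConfig, k: int):
    """Place up to k non-overlapping multi-lobe domains in the section.

    Returns a list of (lobes_abs, bridges) with absolute lobe positions.
    Domains keep at least ``min_domain_separation_um`` between any two
    lobe discs of different domains.  Placement gives up after repeated
    rejections, so crowded configurations may realise fewer than k.
    """
    L = config.tissue_size_um
    placed = []  # list of (lobes_abs, bridges)
    all_lobes = np.empty((0, 3))  # x, y, r of every placed lobe
    for _ in range(k):
        ok = False
        for _attempt in range(300):
            lobes, bridges = _build_lobes(rng, config)
            extent = max(math.hypot(dx, dy) + r for dx, dy, r in lobes) + 10.0
            if 2 * extent >= L:
                continue
            cx = rng.uniform(extent, L - extent)
            cy = rng.uniform(extent, L - extent)
            lob_abs = np.array([(cx + dx, cy + dy, r) for dx, dy, r in lobes])
            if len(all_lobes):
                d = np.hypot(
                    all_lobes[:, 0][:, None] - lob_abs[:, 0][None, :],
                    all_lobes[:, 1][:, None] - lob_abs[:, 1][None, :],
                )
                gap = d - all_lobes[:, 2][:, None] - lob_abs[:, 2][None, :]
                if gap.min() < config.min_domain_separation_um:
                    continue
            placed.append((lob_abs, bridges))
            all_lobes = np.vstack([all_lobes, lob_abs])
            ok = True
            break
        if not ok:
            break  # section is full
    return placed


def _strand_points(
    rng: np.random.Generator, a: np.ndarray, b: np.ndarray, spacing: float
) -> np.ndarray:
    """Jittered 1-cell-wide chain between the boundaries of two lobe discs."""
    ax, ay, ar = a
    bx, by, br = b
    d = math.hypot(bx - ax, by - ay)
    ux, uy = (bx - ax) / d, (by - ay) / d
    ts = np.arange(ar + spacing * 0.5, d - br, spacing)
    if len(ts) == 0:
        return np.empty((0, 2))
    xs = ax + ts * ux + rng.normal(0, 3.0, len(ts)) * (-uy)
    ys = ay + ts * uy + rng.normal(0, 3.0, len(ts)) * ux
    xs += rng.normal(0, 2.0, len(ts)) * ux
    ys += rng.normal(0, 2.0, len(ts)) * uy
    return np.column_stack([xs, ys])


def _ki67_probs(config: CohortConfig, activation: float, treg_presence: float) -> dict[str, float]:
    return {
        s: float(
            expit(
                config.ki67_base_logit[s]
                + activation
                - config.suppression_coeff * treg_presence
            )
        )
        for s in SUBSETS
    }


def generate_section(
    config: CohortConfig,
    activation: float,
    section_index: int,
    section_id: str,
    patient_id: str,
) -> tuple[SectionDataset, SectionTruth]:
    """Generate one section and its ground truth.

    ``section_index`` keys the section's private RNG stream together with
    the cohort seed; identical arguments give byte-identical output.
    """
    rng = np.random.default_rng([config.seed, section_index])
    L = config.tissue_size_um
    density = config.lymphocyte_density_in_domain
    uf = config.undefined_fraction_in_domain

    k = int(rng.integers(config.domain_count_range[0], config.domain_count_range[1] + 1))
    placements = _place_domains(rng, config, k)

    dirichlet_conc = np.asarray(config.composition_dirichlet, dtype=float)

    xs_all: list[np.ndarray] = []
    subset_all: list[np.ndarray] = []
    ki67_all: list[np.ndarray] = []
    block_sizes: list[int] = []

    domain_truths: list[DomainTruth] = []
    polygons = []

    for di, (lobes_abs, bridges) in enumerate(placements):
        polygon = unary_union(
            [Point(x, y).buffer(r, quad_segs=64) for x, y, r in lobes_abs]
        )
        polygons.append(polygon)
        area = polygon.area

        n_lymph = int(rng.poisson(area * density))
        n_undef = int(rng.poisson(area * density * uf / (1.0 - uf)))
        comp_probs = rng.dirichlet(dirichlet_conc)
        subset_counts = rng.multinomial(n_lymph, comp_probs)

        pts = _sample_in_polygon(rng, polygon, n_lymph + n_undef)
        subsets = np.repeat(list(SUBSETS) + [UNDEFINED], list(subset_counts) + [n_undef])

        treg_presence = subset_counts[SUBSETS.index("CD4Treg")] / n_lymph if n_lymph else 0.0
        probs = _ki67_probs(config, activation, treg_presence)

        has_gc = bool(rng.random() < config.gc_probability)
        gx, gy, gr0 = lobes_abs[0]
        gc_disc = (float(gx), float(gy), float(config.gc_radius_frac * gr0)) if has_gc else None

        p_cell = np.array([probs.get(s, 0.0) for s in subsets])
        if has_gc:
            in_gc = (pts[:, 0] - gc_disc[0]) ** 2 + (pts[:, 1] - gc_disc[1]) ** 2 <= gc_disc[2] ** 2
            boost_mask = in_gc & (subsets == "B")
            p_cell[boost_mask] = expit(
                config.ki67_base_logit["B"]
                + config.gc_boost_logit
                + activation
                - config.suppression_coeff * treg_presence
            )
        p_cell[subsets == UNDEFINED] = config.undefined_ki67_rate
        ki67 = rng.random(len(subsets)) < p_cell

        xs_all.append(pts)
        subset_all.append(subsets)
        ki67_all.append(ki67)
        block_sizes.append(len(subsets))

        domain_truths.append(
            DomainTruth(
                domain_id=f"{section_id}_t{di + 1:04d}",
                section_id=section_id,
                polygon=polygon,
                lymph_member_ids=[],
                undefined_member_ids=[],
                counts={},
                ki67_prob=probs,
                has_gc=has_gc,
                gc_disc=gc_disc,
                n_lobes=len(lobes_abs),
                n_bridges=len(bridges),
            )
        )

        # strands bridging lobes of this domain (kept outside the polygon)
        strand_pts = []
        for ia, ib, _gap in bridges:
            strand_pts.append(
                _strand_points(rng, lobes_abs[ia], lobes_abs[ib], config.strand_cell_spacing_um)
            )
        if strand_pts:
            sp = np.concatenate(strand_pts)
            outside = ~shapely.intersects_xy(polygon, sp[:, 0], sp[:, 1])
            sp = sp[outside]
            if len(sp):
                s_subsets = np.asarray(SUBSETS, dtype=object)[
                    rng.choice(len(SUBSETS), size=len(sp), p=comp_probs)
                ]
                s_p = np.array([probs[s] for s in s_subsets])
                s_ki67 = rng.random(len(sp)) < s_p
                xs_all.append(sp)
                subset_all.append(s_subsets.astype(str))
                ki67_all.append(s_ki67)
                block_sizes.append(-len(sp))  # negative marks a strand block

    # background cells across the whole section
    n_bg = int(rng.poisson(L * L * config.background_cell_density))
    bg_pts = np.column_stack([rng.uniform(0, L, n_bg), rng.uniform(0, L, n_bg)])
    bg_lymph = rng.random(n_bg) < config.background_lymphocyte_fraction
    bg_subsets = np.full(n_bg, UNDEFINED, dtype=object)
    mean_probs = dirichlet_conc / dirichlet_conc.sum()
    bg_subsets[bg_lymph] = np.asarray(SUBSETS, dtype=object)[
        rng.choice(len(SUBSETS), size=int(bg_lymph.sum()), p=mean_probs)
    ]
    bg_probs = _ki67_probs(config, activation, 0.0)
    bg_p = np.array(
        [bg_probs.get(s, config.undefined_ki67_rate) for s in bg_subsets]
    )
    bg_ki67 = rng.random(n_bg) < bg_p
    xs_all.append(bg_pts)
    subset_all.append(bg_subsets.astype(str))
    ki67_all.append(bg_ki67)
    block_sizes.append(n_bg)

    xy = np.concatenate(xs_all) if xs_all else np.empty((0, 2))
    subsets = np.concatenate(subset_all) if subset_all else np.empty(0, dtype=str)
    ki67 = np.concatenate(ki67_all) if ki67_all else np.empty(0, dtype=bool)
    n_cells = len(xy)
    cell_ids = np.array([f"{section_id}_c{i + 1:07d}" for i in range(n_cells)], dtype=object)

    # bookkeeping: credit each domain with its own cells and any background
    # cells that landed inside its polygon; record strand cell ids
    labels = np.where(
        subsets == UNDEFINED,
        UNDEFINED,
        np.char.add(
            np.char.add(subsets.astype(str), "_Ki67"), np.where(ki67, "pos", "neg")
        ),
    )
    # blocks were appended as: per-domain cells, optional strand cells
    # (negative size), ..., background last
    offset = 0
    strand_ids: list[str] = []
    domain_block_of: list[tuple[int, int]] = []
    for bi, size in enumerate(block_sizes):
        if size < 0:
            strand_ids.extend(cell_ids[offset : offset - size].tolist())
            offset += -size
        else:
            if bi < len(block_sizes) - 1:  # background is the last block
                domain_block_of.append((offset, offset + size))
            offset += size

    bg_start = n_cells - n_bg
    for di, truth in enumerate(domain_truths):
        start, stop = domain_block_of[di]
        idx = np.arange(start, stop)
        if n_bg:
            inside_bg = shapely.intersects_xy(
                truth.polygon, xy[bg_start:, 0], xy[bg_start:, 1]
            )
            idx = np.concatenate([idx, bg_start + np.flatnonzero(inside_bg)])
        mem_subsets = subsets[idx]
        is_lymph = mem_subsets != UNDEFINED
        truth.lymph_member_ids = cell_ids[idx[is_lymph]].tolist()
        truth.undefined_member_ids = cell_ids[idx[~is_lymph]].tolist()
        mem_labels, mem_counts = np.unique(labels[idx], return_counts=True)
        counts = dict(zip(mem_labels.tolist(), mem_counts.tolist()))
        truth.counts = {lab: int(counts.get(lab, 0)) for lab in ALL_LABELS}

    # marker calls from intended labels (exact phenotyping oracle)
    calls = np.array([MARKER_CALLS[s] for s in subsets], dtype=bool).reshape(n_cells, 4)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cd20": calls[:, 0],
            "cd3": calls[:, 1],
            "cd8": calls[:, 2],
            "foxp3": calls[:, 3],
            "ki67": ki67,
        }
    )

    # tumour annotation: one disc fully inside the tissue square
    frac = rng.uniform(*config.tumour_area_fraction_range)
    r_t = math.sqrt(frac * L * L / math.pi)
    r_t = min(r_t, L * 0.45)
    tcx = rng.uniform(r_t, L - r_t)
    tcy = rng.uniform(r_t, L - r_t)
    tumour = Point(tcx, tcy).buffer(r_t, quad_segs=64)

    dataset = SectionDataset(
        section_id=section_id,
        patient_id=patient_id,
        cells=cells,
        tissue_regions=[box(0.0, 0.0, L, L)],
        tumour_regions=[tumour],
        meta={"generator": "tlsquant.synthetic", "section_index": section_index},
    )
    lab_vals, lab_counts = np.unique(labels, return_counts=True)
    totals = dict(zip(lab_vals.tolist(), (int(c) for c in lab_counts)))
    truth = SectionTruth(
        section_id=section_id,
        patient_id=patient_id,
        activation=float(activation),
        domains=domain_truths,
        strand_cell_ids=strand_ids,
        label_totals={lab: int(totals.get(lab, 0)) for lab in ALL_LABELS},
    )
    return dataset, truth


def iter_cohort(config: CohortConfig):
    """Yield ``(dataset, section_truth)`` pairs one section at a time.

    Activations are Normal(0, ``latent_activation_sd``²), one value per
    patient, shared across that patient's sections — the device that
    couples Ki-67 across subsets within a patient.  Streaming keeps peak
    memory at one section regardless of cohort size.
    """
    rng0 = np.random.default_rng([config.seed, 0])
    activations = rng0.normal(0.0, config.latent_activation_sd, config.n_patients)
    section_index = 1
    for pi in range(config.n_patients):
        patient_id = f"P{pi + 1:03d}"
        for si in range(config.sections_per_patient):
            section_id = f"{patient_id}_S{si + 1}"
            yield generate_section(
                config, activations[pi], section_index, section_id, patient_id
            )
            section_index += 1


def generate_cohort(config: CohortConfig) -> tuple[list[SectionDataset], CohortTruth]:
    """Generate a full cohort in memory; see :func:`iter_cohort`."""
    datasets: list[SectionDataset] = []
    truths: list[SectionTruth] = []
    act_map: dict[str, float] = {}
    for ds, tr in iter_cohort(config):
        datasets.append(ds)
        truths.append(tr)
        act_map[tr.patient_id] = tr.activation
    return datasets, CohortTruth(config=config, activations=act_map, sections=truths)


def domains_from_truth(
    truth: SectionTruth,
    params: QualificationParams | None = None,
    qualified_only: bool = True,
) -> list[TLSDomain]:
    """Build TLS domains directly from planted truth (bypassing detection).

    Useful for studying the metrics/statistics stages at planted-truth
    resolution.  With ``qualified_only`` the real inclusion predicate is
    applied to the truth compositions.
    """
    params = params or QualificationParams()
    out: list[TLSDomain] = []
    for dt in truth.domains:
        comp = DomainComposition(dt.counts)
        member_ids = tuple(sorted(dt.lymph_member_ids))
        cluster = AggregateCluster(
            member_cell_ids=member_ids,
            boundary=dt.polygon,
            centroid=(dt.polygon.centroid.x, dt.polygon.centroid.y),
        )
        result = qualify(
            cluster, comp, params, domain_id=dt.domain_id, section_id=dt.section_id
        )
        if isinstance(result, TLSDomain):
            out.append(result)
        elif not qualified_only:
            out.append(
                TLSDomain(dt.domain_id, dt.section_id, comp, cluster.area_um2, cluster)
            )
    return out


def sample_cohort_compositions(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Composition-level twin of :func:`generate_cohort` (no geometry).

    Draws per-domain phenotype counts from the same distributions the
    spatial generator realises (Poisson cell counts on an approximate
    domain area, Dirichlet-multinomial composition, logistic Ki-67 with
    latent activation, GC boost as a binomial mixture) without placing any
    cells.  Orders of magnitude faster; used for statistical studies that
    need many replicate cohorts.  Returns a per-domain count table and the
    activation map.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 999983])
    conc = np.asarray(config.composition_dirichlet, dtype=float)
    uf = config.undefined_fraction_in_domain
    rows = []
    activations: dict[str, float] = {}
    for pi in range(config.n_patients):
        patient_id = f"P{pi + 1:03d}"
        activation = rng.normal(0.0, config.latent_activation_sd)
        activations[patient_id] = float(activation)
        for si in range(config.sections_per_patient):
            section_id = f"{patient_id}_S{si + 1}"
            k = int(rng.integers(config.domain_count_range[0], config.domain_count_range[1] + 1))
            for di in range(k):
                r0 = rng.uniform(*config.domain_radius_range)
                area = math.pi * r0 * r0
                n_extra = int(rng.poisson(max(config.lobularity - 1.0, 0.0)))
                for _ in range(n_extra):
                    r_i = r0 * rng.uniform(0.55, 0.85)
                    bridged = rng.random() < config.strand_probability
                    # overlapping lobes share area; bridged lobes do not
                    area += math.pi * r_i * r_i * (1.0 if bridged else 0.75)
                n_lymph = int(rng.poisson(area * config.lymphocyte_density_in_domain))
                n_undef = int(
                    rng.poisson(area * config.lymphocyte_density_in_domain * uf / (1 - uf))
                )
                comp_probs = rng.dirichlet(conc)
                subset_counts = rng.multinomial(n_lymph, comp_probs)
                treg_presence = (
                    subset_counts[SUBSETS.index("CD4Treg")] / n_lymph if n_lymph else 0.0
                )
                probs = _ki67_probs(config, activation, treg_presence)
                counts: dict[str, int] = {UNDEFINED: n_undef}
                has_gc = rng.random() < config.gc_probability
                gc_area_frac = min(config.gc_radius_frac**2 * math.pi * r0 * r0 / area, 1.0)
                for s, n_s in zip(SUBSETS, subset_counts):
                    n_s = int(n_s)
                    if s == "B" and has_gc:
                        n_gc = int(rng.binomial(n_s, gc_area_frac))
                        p_gc = float(
                            expit(
                                config.ki67_base_logit["B"]
                                + config.gc_boost_logit
                                + activation
                                - config.suppression_coeff * treg_presence
                            )
                        )
                        pos = int(rng.binomial(n_s - n_gc, probs[s])) + int(
                            rng.binomial(n_gc, p_gc)
                        )
                    else:
                        pos = int(rng.binomial(n_s, probs[s]))
                    counts[f"{s}_Ki67pos"] = pos
                    counts[f"{s}_Ki67neg"] = n_s - pos
                rows.append(
                    {
                        "patient_id": patient_id,
                        "section_id": section_id,
                        "domain_id": f"{section_id}_t{di + 1:04d}",
                        "activation": float(activation),
                        "area_um2": area,
                        **{lab: counts.get(lab, 0) for lab in ALL_LABELS},
                    }
                )
    columns = ["patient_id", "section_id", "domain_id", "activation", "area_um2"] + list(
        ALL_LABELS
    )
    return pd.DataFrame(rows, columns=columns), activations


def domains_from_composition_table(
    table: pd.DataFrame,
    params: QualificationParams | None = None,
    qualified_only: bool = True,
) -> list[TLSDomain]:
    """TLS domains from a composition table (no geometry attached)."""
    params = params or QualificationParams()
    out: list[TLSDomain] = []
    for row in table.itertuples(index=False):
        comp = DomainComposition({lab: getattr(row, lab) for lab in ALL_LABELS})
        ok = comp.n_total >= params.min_cells and comp.n_lymph > params.min_lymph_frac * comp.n_total
        if ok or not qualified_only:
            out.append(
                TLSDomain(row.domain_id, row.section_id, comp, float(row.area_um2), None)
            )
    return out


def config_dict(config: CohortConfig) -> dict:
    """JSON-serialisable view of a config (for manifests)."""
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
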