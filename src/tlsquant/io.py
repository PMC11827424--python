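"""Reading cell tables and region annotations; writing pipeline outputs.

Cell tables are CSV/TSV exports with one row per segmented cell: x/y
centroid coordinates and boolean (or boolean-codeable) positivity columns
for the five markers.  Column names and truth-value codings vary between
platforms, so loading goes through a :class:`TableDialect` column map.

Coordinates are micrometres, origin top-left, y increasing downward (the
microscopy convention); ``unit_scale`` converts pixel-unit exports.

Region annotations (tissue outline, tumour regions) are GeoJSON
FeatureCollections of Polygon/MultiPolygon features in the same µm
coordinate frame, as exported by QuPath-style viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import shapely.affinity
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union


class ConfigurationError(ValueError):
    """A dialect names a column the file does not have."""


class FormatError(ValueError):
    """File contents violate the expected format."""


class EmptyInputError(ValueError):
    """No parseable cell rows."""


_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "pos", "positive", "+"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "neg", "negative", "-", ""}


@dataclass(frozen=True)
class TableDialect:
    """Column mapping and value coding for a cell-table export.

    Marker columns accept 0/1, true/false and pos/neg codings out of the
    box; extend ``true_values``/``false_values`` for other exports.  When
    ``cell_id`` is None, sequential ids ``c0000001`` ... are generated.
    """

    x: str = "x"
    y: str = "y"
    cd20: str = "CD20"
    cd3: str = "CD3"
    cd8: str = "CD8"
    foxp3: str = "FOXP3"
    ki67: str = "KI67"
    cell_id: str | None = None
    sep: str | None = None  # None: infer from extension (.tsv -> tab)
    true_values: frozenset[str] = frozenset(_TRUE_TOKENS)
    false_values: frozenset[str] = frozenset(_FALSE_TOKENS)

    def marker_map(self) -> dict[str, str]:
        return {
            "cd20": self.cd20,
            "cd3": self.cd3,
            "cd8": self.cd8,
            "foxp3": self.foxp3,
            "ki67": self.ki67,
        }


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: µm position plus five boolean marker calls."""

    cell_id: str
    x: float
    y: float
    cd20: bool
    cd3: bool
    cd8: bool
    foxp3: bool
    ki67: bool


@dataclass
class SectionDataset:
    """All loaded data for one tissue section.

    ``cells`` is a DataFrame with columns ``cell_id, x, y, cd20, cd3, cd8,
    foxp3, ki67`` (coordinates µm, markers bool).  Region lists are
    optional shapely polygons in the same frame.
    """

    section_id: str
    patient_id: str
    cells: pd.DataFrame
    tissue_regions: list[Polygon] | None = None
    tumour_regions: list[Polygon] | None = None
    unit_scale: float = 1.0
    n_dropped_rows: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_records(self) -> list[CellRecord]:
        return [CellRecord(**row) for row in self.cells.to_dict("records")]

    def validate_regions(self, tolerance_um: float = 1.0) -> None:
        """Check tumour regions lie within the tissue (buffered) union."""
        if not self.tissue_regions or not self.tumour_regions:
            return
        tissue = unary_union(self.tissue_regions).buffer(tolerance_um)
        for poly in self.tumour_regions:
            if not tissue.covers(poly):
                raise ValueError(
                    "tumour region extends outside the tissue union "
                    f"(tolerance {tolerance_um} µm)"
                )


def _coerce_bool(series: pd.Series, column: str, dialect: TableDialect) -> pd.Series:
    if series.dtype == bool:
        return series
    tokens = series.astype(str).str.strip().str.lower()
    is_true = tokens.isin(dialect.true_values)
    is_false = tokens.isin(dialect.false_values)
    bad = ~(is_true | is_false)
    if bad.any():
        example = series[bad].iloc[0]
        raise FormatError(
            f"column {column!r}: value {example!r} is not coercible to boolean"
        )
    return is_true


def read_cell_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    section_id: str | None = None,
    patient_id: str = "unknown",
    unit_scale: float = 1.0,
    tissue_regions: list[Polygon] | None = None,
    tumour_regions: list[Polygon] | None = None,
) -> SectionDataset:
    """Load a cell-level table into a :class:`SectionDataset`.

    Rows with missing coordinates are dropped and counted in
    ``n_dropped_rows``; the loader never merges or invents cells, so
    ``n_cells + n_dropped_rows`` equals the file's row count.  Marker
    conflicts (e.g. CD20+CD3+) are loaded verbatim — resolving them is the
    phenotyping gate's job.
    """
    path = Path(path)
    dialect = dialect or TableDialect()
    sep = dialect.sep
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep)

    mapping_ = {"x": dialect.x, "y": dialect.y, **dialect.marker_map()}
    if dialect.cell_id is not None:
        mapping_["cell_id"] = dialect.cell_id
    # column matching is case-insensitive (export casing varies by platform)
    by_lower = {c.lower(): c for c in raw.columns}
    missing = [src for src in mapping_.values() if src.lower() not in by_lower]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) {missing} not present in {path.name}; "
            f"available: {list(raw.columns)}"
        )
    mapping_ = {dst: by_lower[src.lower()] for dst, src in mapping_.items()}

    df = pd.DataFrame({dst: raw[src] for dst, src in mapping_.items()})
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    ok = df["x"].notna() & df["y"].notna()
    n_dropped = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no rows with parseable coordinates")

    for marker in ("cd20", "cd3", "cd8", "foxp3", "ki67"):
        df[marker] = _coerce_bool(df[marker], mapping_[marker], dialect)

    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"c{i + 1:07d}" for i in range(len(df))])
    else:
        df["cell_id"] = df["cell_id"].astype(str)
        if df["cell_id"].duplicated().any():
            dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate cell_id {dup!r}")

    df["x"] = df["x"].astype(float) * unit_scale
    df["y"] = df["y"].astype(float) * unit_scale
    df = df[["cell_id", "x", "y", "cd20", "cd3", "cd8", "foxp3", "ki67"]]

    return SectionDataset(
        section_id=section_id or path.stem,
        patient_id=patient_id,
        cells=df,
        tissue_regions=tissue_regions,
        tumour_regions=tumour_regions,
        unit_scale=unit_scale,
        n_dropped_rows=n_dropped,
    )


def read_regions(path: str | Path, kind: str = "tissue", repair: bool = True) -> list[Polygon]:
    """Read a GeoJSON FeatureCollection of polygon annotations.

    MultiPolygon features are split into their parts; holes are preserved.
    Invalid rings get one zero-buffer repair attempt (when ``repair``);
    still-invalid geometry is rejected.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path.name}: expected a GeoJSON FeatureCollection")
    polygons: list[Polygon] = []
    for feature in doc.get("features", []):
        geom = shape(feature["geometry"])
        if isinstance(geom, Polygon):
            parts = [geom]
        elif isinstance(geom, MultiPolygon):
            parts = list(geom.geoms)
        else:
            raise FormatError(
                f"{path.name}: {kind} feature has non-polygon geometry "
                f"{geom.geom_type}"
            )
        for poly in parts:
            if not poly.is_valid:
                if repair:
                    poly = poly.buffer(0)
                if not poly.is_valid or poly.is_empty or poly.geom_type != "Polygon":
                    raise FormatError(f"{path.name}: invalid {kind} polygon ring")
            polygons.append(poly)
    return polygons


def write_regions(polygons, path: str | Path) -> None:
    """Write polygons as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {}, "geometry": mapping(poly)}
        for poly in polygons
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV deterministically: UTF-8, LF, fixed float format."""
    df.to_csv(
        path,
        sep="\t",
        index=False,
        lineterminator="\n",
        float_format="%.10g",
        encoding="utf-8",
    )


def write_outputs(results, out_dir: str | Path) -> dict:
    """Write all tables and the run manifest for a pipeline result.

    ``results`` is a :class:`tlsquant.pipeline.PipelineResult`.  Re-running
    with identical inputs and seed reproduces byte-identical files (the
    manifest carries no timestamps).  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_table(results.domain_table, out_dir / "domains.tsv")
    write_table(results.section_table, out_dir / "sections.tsv")
    write_table(results.correlation_table, out_dir / "correlations.tsv")
    write_table(results.ranking_table, out_dir / "rankings.tsv")

    manifest = dict(results.manifest)
    manifest["outputs"] = [
        "domains.tsv",
        "sections.tsv",
        "correlations.tsv",
        "rankings.tsv",
    ]
    with open(out_dir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def scale_dataset(dataset: SectionDataset, unit_scale: float) -> SectionDataset:
    """Return a copy with coordinates multiplied by ``unit_scale``."""
    cells = dataset.cells.copy()
    cells["x"] *= unit_scale
    cells["y"] *= unit_scale
    tissue = (
        [shapely.affinity.scale(p, unit_scale, unit_scale, origin=(0, 0)) for p in dataset.tissue_regions]
        if dataset.tissue_regions
        else None
    )
    tumour = (
        [shapely.affinity.scale(p, unit_scale, unit_scale, origin=(0, 0)) for p in dataset.tumour_regions]
        if dataset.tumour_regions
        else None
    )
    return replace(
        dataset,
        cells=cells,
        tissue_regions=tissue,
        tumour_regions=tumour,
        unit_scale=dataset.unit_scale * unit_scale,
    )
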