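"""Phenotype gating: five boolean marker calls to one of nine cell classes.

Each segmented cell carries boolean positivity calls for CD20, CD3, CD8,
Foxp3 and Ki-67 (DAPI positivity is implicit in the cell's existence).
Cells are gated into four mutually exclusive lymphocyte subsets —

* ``B``        : CD20+ CD3−
* ``CD8T``     : CD3+ CD8+        (Foxp3 ignored for this gate)
* ``CD4Tconv`` : CD3+ CD8− Foxp3−
* ``CD4Tregs`` are ``CD4Treg``: CD3+ CD8− Foxp3+

— every other marker combination is ``undefined``.  The four subsets are
each split by Ki-67 status, giving eight lymphocyte classes; undefined
cells carry no Ki-67 sub-classification, for nine classes in total.

CD20+CD3+ double positives fall through to the T-cell gates because the
B gate explicitly requires CD3−.  CD3+CD8− cells are treated as CD4
T cells (CD4 itself is not in the panel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: lymphocyte subsets, in canonical reporting order
SUBSETS: tuple[str, ...] = ("B", "CD8T", "CD4Tconv", "CD4Treg")

UNDEFINED = "undefined"

#: the eight lymphocyte classes (subset × Ki-67 stratum)
LYMPHOCYTE_LABELS: tuple[str, ...] = tuple(
    f"{s}_Ki67{k}" for s in SUBSETS for k in ("pos", "neg")
)

#: all nine phenotype classes
ALL_LABELS: tuple[str, ...] = LYMPHOCYTE_LABELS + (UNDEFINED,)

#: marker columns a labelled table must provide
MARKER_COLUMNS = ("cd20", "cd3", "cd8", "foxp3", "ki67")


@dataclass(frozen=True)
class PhenotypeLabel:
    """One of the nine phenotype classes.

    ``subset`` is one of :data:`SUBSETS` or ``"undefined"``; ``ki67`` is
    False by convention whenever ``subset`` is undefined.
    """

    subset: str
    ki67: bool = False

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS and self.subset != UNDEFINED:
            raise ValueError(f"unknown subset {self.subset!r}")
        if self.subset == UNDEFINED and self.ki67:
            raise ValueError("undefined cells carry no Ki-67 sub-classification")

    @property
    def label(self) -> str:
        """Canonical string form, e.g. ``"B_Ki67pos"`` or ``"undefined"``."""
        if self.subset == UNDEFINED:
            return UNDEFINED
        return f"{self.subset}_Ki67{'pos' if self.ki67 else 'neg'}"


def classify_cell(
    cd20: bool, cd3: bool, cd8: bool, foxp3: bool, ki67: bool = False
) -> PhenotypeLabel:
    """Gate a single cell's marker calls into a phenotype class.

    A total function over the 32 boolean marker combinations: exactly one
    class results from every combination.
    """
    if cd3:
        if cd8:
            subset = "CD8T"
        elif foxp3:
            subset = "CD4Treg"
        else:
            subset = "CD4Tconv"
    elif cd20:
        subset = "B"
    else:
        return PhenotypeLabel(UNDEFINED)
    return PhenotypeLabel(subset, bool(ki67))


def assign_subsets(cells: pd.DataFrame) -> pd.Series:
    """Vectorised subset gate over a marker table.

    ``cells`` must carry boolean columns :data:`MARKER_COLUMNS`.  Returns a
    Series of subset names aligned to ``cells``.
    """
    cd20 = cells["cd20"].to_numpy(dtype=bool)
    cd3 = cells["cd3"].to_numpy(dtype=bool)
    cd8 = cells["cd8"].to_numpy(dtype=bool)
    foxp3 = cells["foxp3"].to_numpy(dtype=bool)
    subset = np.select(
        [cd3 & cd8, cd3 & foxp3, cd3, cd20],
        ["CD8T", "CD4Treg", "CD4Tconv", "B"],
        default=UNDEFINED,
    )
    return pd.Series(subset, index=cells.index, name="subset")


def phenotype_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Label every cell in a marker table.

    Returns a copy of ``cells`` with two added columns: ``subset`` and
    ``label`` (one of the nine classes; Ki-67 stratification only for the
    four lymphocyte subsets).
    """
    out = cells.copy()
    subset = assign_subsets(cells)
    ki67 = cells["ki67"].to_numpy(dtype=bool)
    is_lymph = (subset != UNDEFINED).to_numpy()
    strata = np.where(ki67, "pos", "neg")
    label = np.where(
        is_lymph,
        np.char.add(np.char.add(subset.to_numpy(dtype=str), "_Ki67"), strata),
        UNDEFINED,
    )
    out["subset"] = subset
    out["label"] = pd.Categorical(label, categories=list(ALL_LABELS))
    return out


def phenotype_section(dataset) -> pd.DataFrame:
    """Label a loaded section; see :func:`phenotype_cells`.

    Accepts a :class:`~tlsquant.io.SectionDataset`; returns the labelled
    cell table.  Per-label counts always sum to the cell count.
    """
    return phenotype_cells(dataset.cells)


def label_counts(labelled: pd.DataFrame) -> dict[str, int]:
    """Counts of the nine classes in a labelled table (zeros included)."""
    vc = labelled["label"].value_counts()
    return {lab: int(vc.get(lab, 0)) for lab in ALL_LABELS}
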