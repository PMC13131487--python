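"""Subtype-restricted GPCR expression screen.

Given a gene × DRG-subtype expression summary matrix (normalized subtype
means or fraction-of-cells-expressing — declared by the caller, never
assumed) and subtype class labels, return the genes whose expression is
restricted to the CGRP+ nociceptor subtypes: expressed in at least one CGRP+
subtype and not expressed in any LTMR or proprioceptor subtype. Subtypes of
class "other" (e.g. TrpM8+, MrgprD+) neither qualify nor disqualify a gene
by default; a strict mode also treats them as exclusion classes.

Two thresholds make "expressed in" and "not expressed in" independent
judgments: a gene counts as on where its value ≥ ``on_threshold`` and
violates restriction where a value in an exclusion subtype ≥
``off_threshold``. With ``off == on`` and a binary matrix the screen reduces
to exact set logic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.io import mmread

__all__ = [
    "validate_annotation",
    "is_expressed",
    "restriction_screen",
    "breadth_profile",
    "load_expression_matrix",
    "load_annotation",
]

EXCLUSION_CLASSES = ("LTMR", "proprioceptor")
KNOWN_CLASSES = ("CGRP", "LTMR", "proprioceptor", "other")


def validate_annotation(annotation: pd.DataFrame) -> pd.Series:
    """Check subtype annotations and return the subtype_id → class mapping.

    A valid screen needs unique subtype ids, known class labels, and at least
    one CGRP and one LTMR subtype.
    """
    required = {"subtype_id", "class"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if annotation["subtype_id"].duplicated().any():
        raise ValueError("duplicate subtype ids in annotation")
    unknown = set(annotation["class"]) - set(KNOWN_CLASSES)
    if unknown:
        raise ValueError(f"unknown subtype classes: {sorted(unknown)}")
    classes = annotation.set_index("subtype_id")["class"]
    if (classes == "CGRP").sum() < 1 or (classes == "LTMR").sum() < 1:
        raise ValueError("screen needs ≥1 CGRP and ≥1 LTMR subtype")
    return classes


def is_expressed(value: float, on_threshold: float) -> bool:
    """A gene counts as expressed where its summary ≥ threshold (inclusive)."""
    if on_threshold < 0:
        raise ValueError("on_threshold must be nonnegative")
    if value < 0:
        raise ValueError("expression summaries must be nonnegative")
    return value >= on_threshold


def restriction_screen(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    on_threshold: float = 0.1,
    off_threshold: float = 0.1,
    strict_other: bool = False,
) -> pd.DataFrame:
    """Screen for genes restricted to CGRP+ subtypes.

    Parameters
    ----------
    matrix
        Genes (rows) × subtypes (columns), nonnegative expression summaries.
    annotation
        Subtype table with ``subtype_id`` and ``class`` columns covering
        every matrix column.
    on_threshold, off_threshold
        Inclusive on-call threshold and exclusive off-call threshold (a value
        ≥ off_threshold in an exclusion subtype is a violation). Requires
        ``off_threshold ≤ on_threshold``.
    strict_other
        Also treat class-"other" subtypes as exclusion classes.

    Returns a frame indexed like ``matrix`` with columns ``restricted``
    (bool), ``breadth`` (number of CGRP+ subtypes expressing), and the
    semicolon-joined ``on_subtypes`` and ``off_violations`` lists.
    """
    if matrix.shape[0] == 0:
        raise ValueError("gene universe is empty")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in matrix")
    if on_threshold < 0 or off_threshold < 0:
        raise ValueError("thresholds must be nonnegative")
    if off_threshold > on_threshold:
        raise ValueError("off_threshold must be ≤ on_threshold")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression summaries must be nonnegative")
    classes = validate_annotation(annotation)
    missing = [c for c in matrix.columns if c not in classes.index]
    if missing:
        raise ValueError(f"matrix columns missing from annotation: {missing}")

    exclusion = list(EXCLUSION_CLASSES) + (["other"] if strict_other else [])
    cgrp_cols = [c for c in matrix.columns if classes[c] == "CGRP"]
    off_cols = [c for c in matrix.columns if classes[c] in exclusion]

    on = matrix[cgrp_cols] >= on_threshold
    viol = matrix[off_cols] >= off_threshold
    breadth = on.sum(axis=1)
    restricted = (breadth >= 1) & ~viol.any(axis=1)
    return pd.DataFrame(
        {
            "restricted": restricted,
            "breadth": breadth.astype(int),
            # sorted so output is invariant to matrix column order
            "on_subtypes": on.apply(
                lambda row: ";".join(sorted(c for c in cgrp_cols if row[c])),
                axis=1,
            ),
            "off_violations": viol.apply(
                lambda row: ";".join(sorted(c for c in off_cols if row[c])),
                axis=1,
            ),
        },
        index=matrix.index.rename("gene"),
    )


def breadth_profile(results: pd.DataFrame) -> pd.Series:
    """Histogram of breadth (CGRP+ subtypes expressing) over restricted genes.

    Counts sum to the number of restricted genes; an empty restricted set
    yields an empty histogram. Breadth 1 means exclusive expression in a
    single CGRP+ subtype.
    """
    restricted = results.loc[results["restricted"], "breadth"]
    return restricted.value_counts().sort_index().rename("n_genes")


def load_expression_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    subtypes_path: str | Path | None = None,
) -> pd.DataFrame:
    """Load a genes × subtypes matrix from delimited text, or from a
    matrix-market triplet file with sidecar gene/subtype id lists."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or subtypes_path is None:
            raise ValueError("matrix-market input needs gene and subtype sidecars")
        genes = Path(genes_path).read_text().split()
        subtypes = Path(subtypes_path).read_text().split()
        mat = pd.DataFrame(
            mmread(path).toarray(), index=genes, columns=subtypes
        )
    else:
        mat = pd.read_csv(path, index_col=0)
    if mat.index.duplicated().any():
        raise ValueError("duplicate gene ids in matrix file")
    return mat


def load_annotation(path: str | Path) -> pd.DataFrame:
    annotation = pd.read_csv(path)
    validate_annotation(annotation)
    return annotation
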