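"""Tissue-expression categorization and preferential-expression detection.

Gene x tissue expression matrices (FPKM for fly, TPM for human) are binned
into five categorical levels with species-specific edges, sub-tissues are
aggregated to reporting tissues by median, and a tissue is called
preferentially expressed for a gene when its value exceeds Q3 + 1.5*IQR of
that gene's values across all tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EXPRESSION_BIN_EDGES, EXPRESSION_CATEGORIES


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x tissues matrix with its unit and species.

    ``grouping`` maps sub-tissue column names to reporting tissues; columns
    not in the map pass through unchanged during aggregation.
    """

    values: pd.DataFrame
    unit: str = "FPKM"
    species: str = "fly"
    grouping: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.species not in EXPRESSION_BIN_EDGES:
            raise ValueError(f"unknown species {self.species!r}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be nonnegative")
        expected = {"fly": "FPKM", "human": "TPM"}[self.species]
        if self.unit != expected:
            raise ValueError(
                f"unit {self.unit!r} inconsistent with species {self.species!r}"
            )


def bin_expression(value: float, species: str) -> str:
    """Categorical expression level for one value.

    Fly (FPKM) edges 10/100/500/1000, human (TPM) edges 3/10/25/100;
    intervals are left-closed, right-open (exactly 10 FPKM is "low")."""
    if species not in EXPRESSION_BIN_EDGES:
        raise ValueError(f"unknown species {species!r}")
    if value < 0:
        raise ValueError("expression value must be nonnegative")
    edges = EXPRESSION_BIN_EDGES[species]
    idx = int(np.searchsorted(edges, value, side="right"))
    return EXPRESSION_CATEGORIES[idx]


def bin_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Apply :func:`bin_expression` elementwise (after any aggregation)."""
    matrix.validate()
    edges = EXPRESSION_BIN_EDGES[matrix.species]
    idx = np.searchsorted(edges, matrix.values.to_numpy(dtype=float), side="right")
    cats = np.asarray(EXPRESSION_CATEGORIES, dtype=object)[idx]
    return pd.DataFrame(cats, index=matrix.values.index, columns=matrix.values.columns)


def aggregate_subtissues(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse sub-tissue columns to reporting tissues by median.

    Aggregation happens on raw values, before binning; binning first would
    not commute with the median and is deliberately unsupported."""
    matrix.validate()
    if not matrix.grouping:
        return ExpressionMatrix(
            values=matrix.values.copy(), unit=matrix.unit, species=matrix.species
        )
    missing = set(matrix.grouping) - set(matrix.values.columns)
    if missing:
        raise ValueError(f"grouping names absent sub-tissues: {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for sub, rep in matrix.grouping.items():
        groups.setdefault(rep, []).append(sub)
    for rep, members in groups.items():
        if not members:
            raise ValueError(f"empty sub-tissue group {rep!r}")
    out = {}
    for col in matrix.values.columns:
        if col not in matrix.grouping:
            out[col] = matrix.values[col]
    for rep, members in groups.items():
        out[rep] = matrix.values[members].median(axis=1)
    return ExpressionMatrix(
        values=pd.DataFrame(out), unit=matrix.unit, species=matrix.species
    )


def preferential_tissues(row) -> list:
    """Tissues whose value strictly exceeds Q3 + 1.5*IQR of the gene's row.

    Quartiles use linear interpolation at rank q*(n-1).  A constant row
    yields no preferential tissue (the threshold equals the constant and the
    comparison is strict)."""
    row = pd.Series(row, dtype=float) if not isinstance(row, pd.Series) else row.astype(float)
    if row.size < 3:
        raise ValueError("need at least 3 tissues to assess preferential expression")
    q1, q3 = np.quantile(row.to_numpy(), [0.25, 0.75])
    threshold = q3 + 1.5 * (q3 - q1)
    return list(row.index[row > threshold])


def preferential_matrix(matrix: ExpressionMatrix) -> dict[str, list]:
    """Per-gene preferential tissues over the (aggregated) matrix."""
    matrix.validate()
    return {
        gene: preferential_tissues(matrix.values.loc[gene])
        for gene in matrix.values.index
    }


def expression_summary(
    categories: pd.DataFrame,
    neuronal_tissues: list[str],
) -> dict[str, int]:
    """Headline counts over a binned category matrix.

    A gene is "expressed" in a tissue when its category is not "none".
    Counts reported: expressed in >=1 tissue, in all tissues (ubiquitous),
    in >=1 non-neuronal tissue, and in zero neuronal tissues.
    """
    unknown = set(neuronal_tissues) - set(categories.columns)
    if unknown:
        raise ValueError(f"neuronal tissues absent from matrix: {sorted(unknown)}")
    expressed = categories != "none"
    non_neuronal = [c for c in categories.columns if c not in neuronal_tissues]
    any_tissue = expressed.any(axis=1)
    summary = {
        "n_genes": int(len(categories)),
        "expressed_any": int(any_tissue.sum()),
        "ubiquitous": int(expressed.all(axis=1).sum()),
        "expressed_non_neuronal": int(expressed[non_neuronal].any(axis=1).sum())
        if non_neuronal
        else 0,
        "no_neuronal": int(
            (~expressed[neuronal_tissues].any(axis=1)).sum()
        )
        if neuronal_tissues
        else int(len(categories)),
    }
    # partition consistency: expressed-in->=1 is the complement of expressed-nowhere
    assert summary["expressed_any"] == summary["n_genes"] - int((~any_tissue).sum())
    return summary
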