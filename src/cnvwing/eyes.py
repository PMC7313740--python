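"""Eye-phenotype severity analysis.

Per-fly ommatidial-disorganization scores from eye-specific knockdown are
normalized as fold change (FC) to the control median, categorized by
severity, tested per line against control with a one-tailed Mann-Whitney
test (BH-corrected across lines), and compared across wing-phenotype
categories with a Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EYE_CATEGORIES, EYE_FC_EDGES
from .stats import KruskalResult, bh_adjust, kruskal_wallis, mann_whitney, pairwise_wilcoxon

EYE_SCORE_COLUMNS = ["line_id", "homolog", "library", "score"]

#: Wing-category axis for eye/wing concordance; "no phenotype" is split into
#: lines with no defect at all and lines with only a size defect.
CONCORDANCE_GROUPS = (
    "no_phenotype",
    "size_defect",
    "mild",
    "moderate",
    "severe",
    "lethal",
)


def normalize_fc(scores, control_scores) -> np.ndarray:
    """Per-fly fold change: score / median(control scores)."""
    scores = np.asarray(scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if control.size == 0:
        raise ValueError("control scores are empty")
    med = float(np.median(control))
    if med <= 0:
        raise ValueError("control median must be positive")
    return scores / med


def categorize_eye(median_fc: float) -> str:
    """Severity category for a line's median fold change.

    [0, 1.1] no_change; (1.1, 1.5] mild; (1.5, 2.0] moderate; (2.0, inf)
    severe.  Interval upper bounds are closed (a median FC of exactly 1.1
    is still "no change")."""
    if median_fc < 0:
        raise ValueError("fold change must be nonnegative")
    idx = int(np.searchsorted(EYE_FC_EDGES, median_fc, side="left"))
    return EYE_CATEGORIES[idx]


@dataclass
class EyeCategoryResult:
    table: pd.DataFrame  # line_id, homolog, n, median_fc, mean_fc, category, p, q


def analyze_eye_scores(scores: pd.DataFrame, controls: pd.DataFrame) -> EyeCategoryResult:
    """Normalize, categorize and test every line against its library control.

    ``scores``/``controls`` columns: line_id, homolog, library, score.  The
    one-tailed (greater) Mann-Whitney p-values are BH-corrected across all
    lines in the table.
    """
    for name, df in (("scores", scores), ("controls", controls)):
        missing = set(EYE_SCORE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"eye {name} missing columns: {sorted(missing)}")
        if (df["score"] < 0).any():
            raise ValueError(f"eye {name} contain negative scores")
    rows = []
    for (line, lib), g in scores.groupby(["line_id", "library"], sort=True):
        ctrl = controls[controls["library"] == lib]["score"].to_numpy(dtype=float)
        if ctrl.size == 0:
            raise ValueError(f"no control scores for library {lib!r}")
        fc = normalize_fc(g["score"], ctrl)
        ctrl_fc = normalize_fc(ctrl, ctrl)
        res = mann_whitney(fc, ctrl_fc, alternative="greater")
        med = float(np.median(fc))
        rows.append(
            {
                "line_id": line,
                "homolog": g["homolog"].iloc[0],
                "library": lib,
                "n": len(fc),
                "median_fc": med,
                "mean_fc": float(np.mean(fc)),
                "category": categorize_eye(med),
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no eye scores to analyze")
    table["q"] = bh_adjust(table["p"])
    return EyeCategoryResult(table=table)


@dataclass
class ConcordanceResult:
    groups: dict[str, list[float]]
    kruskal: KruskalResult
    posthoc: list[dict]
    dropped: list[str]


def eye_wing_concordance(
    line_fc: pd.Series,
    wing_category: pd.Series,
) -> ConcordanceResult:
    """Kruskal-Wallis comparison of per-line average eye FC across wing categories.

    ``line_fc`` maps line_id to its average fold change; ``wing_category``
    maps line_id to one of the six concordance groups.  Groups with no lines
    are dropped with a warning (reducing df); post-hoc pairwise Wilcoxon
    tests with BH correction are reported alongside the omnibus test.
    """
    missing = set(line_fc.index) - set(wing_category.index)
    if missing:
        raise ValueError(f"lines without a wing category: {sorted(missing)[:5]}")
    bad = set(wing_category.unique()) - set(CONCORDANCE_GROUPS)
    if bad:
        raise ValueError(f"unknown wing categories: {sorted(bad)}")
    groups: dict[str, list[float]] = {}
    dropped: list[str] = []
    for cat in CONCORDANCE_GROUPS:
        lines = wing_category.index[wing_category == cat]
        vals = line_fc.reindex(lines).dropna()
        if len(vals) == 0:
            dropped.append(cat)
        else:
            groups[cat] = vals.to_list()
    if dropped:
        warnings.warn(
            f"wing categories with no lines dropped: {dropped}", stacklevel=2
        )
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty wing categories")
    kw = kruskal_wallis(list(groups.values()))
    posthoc = pairwise_wilcoxon(groups)
    return ConcordanceResult(groups=groups, kruskal=kw, posthoc=posthoc, dropped=dropped)
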