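"""Quantitative wing morphometry.

Wing area and six vein lengths (L2-L5, ACV, PCV) per RNAi line are compared
against the matched control of the same library (GD vs KK) and sex with
two-tailed Mann-Whitney tests, Benjamini-Hochberg corrected within one sex,
and summarized per homolog with a discordance rule for disagreeing lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LIBRARIES, MEASURES
from .stats import bh_adjust, mann_whitney

MEASUREMENT_COLUMNS = ["line_id", "homolog", "library", "sex", "wing_id"] + list(MEASURES)

#: Line-level verdict severity for homolog aggregation, most severe first.
VERDICT_ORDER = ("lethal", "severe", "moderate", "mild", "size_defect", "no_phenotype")


def validate_measurements(table: pd.DataFrame) -> None:
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    vals = table[list(MEASURES)].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("all measurements must be positive")
    bad_lib = set(table["library"]) - {f"control_{l}" for l in LIBRARIES} - set(LIBRARIES)
    if bad_lib:
        raise ValueError(f"unknown libraries: {sorted(bad_lib)}")


def _control_values(
    table: pd.DataFrame, library: str, sex: str, measure: str
) -> np.ndarray:
    ctrl_name = f"control_{library}"
    ctrl = table[(table["library"] == ctrl_name) & (table["sex"] == sex)]
    if ctrl.empty:
        raise ValueError(f"no matched control {ctrl_name!r} for sex {sex!r}")
    return ctrl[measure].to_numpy(dtype=float)


def compare_measurements(
    table: pd.DataFrame,
    sex: str = "F",
    alpha: float = 0.05,
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every (line, measure) against matched control.

    The BH family is all line x measure tests within the given sex.  The
    direction (smaller/larger/none) is decided by the median ratio once the
    adjusted q falls below ``alpha``.

    Returns one row per (line, measure): n_line, n_control, median_ratio,
    U, p, q, direction.
    """
    validate_measurements(table)
    sub = table[(table["sex"] == sex) & (table["library"].isin(LIBRARIES))]
    rows = []
    for (line, lib), g in sub.groupby(["line_id", "library"], sort=True):
        for measure in measures:
            ctrl = _control_values(table, lib, sex, measure)
            vals = g[measure].to_numpy(dtype=float)
            res = mann_whitney(vals, ctrl, "two-sided")
            ratio = float(np.median(vals) / np.median(ctrl))
            rows.append(
                {
                    "line_id": line,
                    "homolog": g["homolog"].iloc[0],
                    "library": lib,
                    "sex": sex,
                    "measure": measure,
                    "n_line": len(vals),
                    "n_control": len(ctrl),
                    "median_ratio": ratio,
                    "U": res.u,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError(f"no RNAi lines with sex {sex!r} to test")
    out["q"] = bh_adjust(out["p"])
    out["direction"] = "none"
    sig = out["q"] < alpha
    out.loc[sig & (out["median_ratio"] < 1), "direction"] = "smaller"
    out.loc[sig & (out["median_ratio"] > 1), "direction"] = "larger"
    return out


@dataclass
class HomologSummary:
    homolog: str
    verdict: str
    n_lines: int
    discordant: bool
    reason: str


def _line_verdict(qual_label: str | None, directions: set[str]) -> str:
    """Collapse one line's qualitative cluster label and quantitative
    directions into a single verdict."""
    has_size = bool(directions & {"smaller", "larger"})
    if qual_label in ("lethal", "severe", "moderate", "mild"):
        return qual_label
    if has_size:
        return "size_defect"
    return "no_phenotype"


def summarize_homologs(
    quant: pd.DataFrame,
    qual_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate per-line results to homolog level with the discordance rule.

    ``quant`` is the output of :func:`compare_measurements`; ``qual_labels``
    maps line_id to its qualitative severity cluster label (optional).
    A homolog is discordant when (a) one of its lines shows no qualitative or
    quantitative phenotype while another shows any, or (b) its lines disagree
    on the direction of a size change (smaller vs larger).  The homolog
    verdict is the most severe of its line verdicts.
    """
    qual_labels = qual_labels if qual_labels is not None else pd.Series(dtype=object)
    line_dir = quant.groupby("line_id")["direction"].agg(set)
    line_homolog = quant.groupby("line_id")["homolog"].first()

    lines = sorted(set(line_dir.index) | set(qual_labels.index))
    verdicts = {}
    for line in lines:
        dirs = line_dir.get(line, set())
        label = qual_labels.get(line)
        verdicts[line] = _line_verdict(label, dirs)

    rows = []
    for homolog, grp in line_homolog.groupby(line_homolog):
        its_lines = list(grp.index)
        vs = [verdicts[l] for l in its_lines]
        best = min(vs, key=VERDICT_ORDER.index)
        discordant, reason = False, ""
        if len(its_lines) > 1:
            if "no_phenotype" in vs and any(v != "no_phenotype" for v in vs):
                discordant, reason = True, "phenotype_vs_none"
            else:
                dirs = set().union(*(line_dir.get(l, set()) for l in its_lines))
                if {"smaller", "larger"} <= dirs:
                    discordant, reason = True, "size_direction"
        rows.append(
            {
                "homolog": homolog,
                "verdict": best,
                "n_lines": len(its_lines),
                "discordant": discordant,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
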