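"""Larval wing-disc cellular assays.

Per-disc counts of proliferating (pH3-positive) and apoptotic
(dcp1-positive) cells are normalized to the control median and tested per
line with two-tailed Mann-Whitney tests, BH-corrected within one marker.
Discs with staining too widespread to count are carried as censored and
excluded from testing but reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MARKERS
from .stats import bh_adjust, mann_whitney

CELL_COUNT_COLUMNS = ["line_id", "homolog", "sex", "disc_id", "marker", "count", "censored"]


def validate_cell_counts(table: pd.DataFrame) -> None:
    missing = set(CELL_COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cell count table missing columns: {sorted(missing)}")
    bad = set(table["marker"]) - set(MARKERS)
    if bad:
        raise ValueError(f"unknown markers: {sorted(bad)}")
    counts = table.loc[~table["censored"].astype(bool), "count"]
    if (counts < 0).any() or not np.allclose(counts, counts.astype(int)):
        raise ValueError("counts must be nonnegative integers")


@dataclass
class CountStatResult:
    line_id: str
    marker: str
    n_line: int
    n_control: int
    n_censored: int
    normalized_median: float | None
    p: float | None
    direction: str


def count_stat(
    line_counts,
    control_counts,
    marker: str,
    n_censored: int = 0,
    alpha: float = 0.05,
    q: float | None = None,
) -> CountStatResult:
    """Compare one line's usable disc counts against control.

    Normalization is count / median(control).  When every line disc is
    censored no test is run; the censored count is still reported.  The
    direction is decided from the BH-adjusted ``q`` when supplied (else the
    raw p) together with the median ratio.
    """
    control = np.asarray(control_counts, dtype=float)
    if control.size == 0:
        raise ValueError("control counts are empty")
    ctrl_med = float(np.median(control))
    if ctrl_med <= 0:
        raise ValueError("control median must be positive")
    line = np.asarray(line_counts, dtype=float)
    if line.size == 0:
        return CountStatResult(
            line_id="", marker=marker, n_line=0, n_control=control.size,
            n_censored=n_censored, normalized_median=None, p=None, direction="none",
        )
    norm = line / ctrl_med
    res = mann_whitney(line, control, "two-sided")
    med = float(np.median(norm))
    crit = q if q is not None else res.p
    if crit < alpha and med > 1:
        direction = "increased"
    elif crit < alpha and med < 1:
        direction = "decreased"
    else:
        direction = "none"
    return CountStatResult(
        line_id="", marker=marker, n_line=line.size, n_control=control.size,
        n_censored=n_censored, normalized_median=med, p=res.p, direction=direction,
    )


def analyze_cell_counts(
    table: pd.DataFrame,
    control_line: str = "control",
    alpha: float = 0.05,
    sex: str | None = None,
) -> pd.DataFrame:
    """Per-line, per-marker count statistics with BH correction within marker.

    ``control_line`` names the control rows in ``line_id``.  When ``sex`` is
    given, rows are restricted to that sex (and controls matched by sex).
    Returns one row per (line, marker) with normalized median, p, q and
    direction; lines whose discs are all censored carry p = NaN.
    """
    validate_cell_counts(table)
    if sex is not None:
        table = table[table["sex"] == sex]
    ctrl = table[table["line_id"] == control_line]
    if ctrl.empty:
        raise ValueError(f"no control rows with line_id {control_line!r}")
    rows = []
    for marker in MARKERS:
        cm = ctrl[(ctrl["marker"] == marker) & ~ctrl["censored"].astype(bool)]
        if cm.empty:
            continue
        control_counts = cm["count"].to_numpy(dtype=float)
        lines = table[(table["marker"] == marker) & (table["line_id"] != control_line)]
        for line, g in lines.groupby("line_id", sort=True):
            cens = int(g["censored"].astype(bool).sum())
            usable = g.loc[~g["censored"].astype(bool), "count"].to_numpy(dtype=float)
            r = count_stat(usable, control_counts, marker, n_censored=cens, alpha=alpha)
            rows.append(
                {
                    "line_id": line,
                    "homolog": g["homolog"].iloc[0],
                    "marker": marker,
                    "n_line": r.n_line,
                    "n_control": r.n_control,
                    "n_censored": cens,
                    "normalized_median": r.normalized_median,
                    "p": r.p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable (line, marker) groups")
    out["q"] = np.nan
    for marker in MARKERS:
        mask = (out["marker"] == marker) & out["p"].notna()
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"])
    out["direction"] = "none"
    sig = out["q"] < alpha
    out.loc[sig & (out["normalized_median"] > 1), "direction"] = "increased"
    out.loc[sig & (out["normalized_median"] < 1), "direction"] = "decreased"
    return out


def sex_stratified_stat(
    table: pd.DataFrame,
    line: str,
    control_line: str = "control",
    alpha: float = 0.05,
) -> dict:
    """Per-sex count statistics for one line with a sex-discordance flag.

    Each sex is tested against the sex-matched control.  The line is flagged
    sex-discordant for a marker when exactly one sex reaches significance.
    Missing sexes yield a partial result with a warning.
    """
    validate_cell_counts(table)
    sexes = sorted(set(table.loc[table["line_id"] == line, "sex"]))
    if not sexes:
        raise ValueError(f"no rows for line {line!r}")
    if len(sexes) < 2:
        warnings.warn(f"line {line!r} observed in one sex only", stacklevel=2)
    results: dict[str, pd.DataFrame] = {}
    for sx in sexes:
        sub = table[(table["line_id"].isin([line, control_line])) & (table["sex"] == sx)]
        res = analyze_cell_counts(sub, control_line=control_line, alpha=alpha)
        results[sx] = res[res["line_id"] == line]
    flags: dict[str, bool] = {}
    for marker in MARKERS:
        sig = []
        for sx in sexes:
            r = results[sx][results[sx]["marker"] == marker]
            if len(r) == 1 and pd.notna(r["q"].iloc[0]):
                sig.append(bool(r["q"].iloc[0] < alpha))
        flags[marker] = len(sig) == 2 and sum(sig) == 1
    return {"per_sex": results, "sex_discordant": flags}
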