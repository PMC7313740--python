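"""Homolog-level summary assembly.

Collects per-stage output tables from a run directory into one dossier row
per homolog plus headline counts.  Stages that were not run are marked
absent rather than imputed, and the counts are recomputed from the dossier
rows so the JSON summary can never drift from the table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

#: Stage output files consumed, in display order.
STAGE_FILES = {
    "clusters": "clusters.tsv",
    "quant": "quant_stats.tsv",
    "eye": "eye_categories.tsv",
    "cells": "cell_stats.tsv",
}

#: Lethal lines are excluded from quantitative totals; severe lines are
#: additionally excluded from L3 vein-length totals.
_QUANT_EXCLUDE = {"lethal"}
_L3_EXCLUDE = {"lethal", "severe"}


def _load(indir: Path, name: str) -> pd.DataFrame | None:
    path = indir / STAGE_FILES[name]
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", comment="#")


def build_summary(indir) -> tuple[pd.DataFrame, dict]:
    """One dossier row per homolog plus recomputed headline counts.

    Requires at least one stage output in ``indir``; raises when homolog
    metadata conflicts between stages.
    """
    indir = Path(indir)
    stages = {name: _load(indir, name) for name in STAGE_FILES}
    if all(df is None for df in stages.values()):
        raise FileNotFoundError(f"no stage outputs found in {indir}")

    # homolog -> line map, checked for conflicts across stages
    line_homolog: dict[str, str] = {}
    for name, df in stages.items():
        if df is None or "homolog" not in df.columns or "line_id" not in df.columns:
            continue
        for line, hom in df[["line_id", "homolog"]].itertuples(index=False):
            prev = line_homolog.get(line)
            if prev is not None and prev != hom:
                raise ValueError(
                    f"conflicting homolog for line {line!r}: {prev!r} vs {hom!r}"
                )
            line_homolog[line] = hom

    clusters = stages["clusters"]
    quant = stages["quant"]
    eye = stages["eye"]
    cells = stages["cells"]

    homologs = sorted(set(line_homolog.values()))
    rows = []
    for hom in homologs:
        lines = [l for l, h in line_homolog.items() if h == hom]
        row: dict = {"homolog": hom, "n_lines": len(lines)}

        if clusters is not None:
            labs = clusters[clusters["line_id"].isin(lines)]["label"]
            row["wing_cluster"] = ";".join(sorted(set(labs))) if len(labs) else "absent"
        else:
            row["wing_cluster"] = "absent"

        for measure, col in (("area", "area_direction"), ("L3", "L3_direction")):
            if quant is not None:
                sub = quant[(quant["homolog"] == hom) & (quant["measure"] == measure)]
                dirs = set(sub["direction"]) - {"none"}
                row[col] = ";".join(sorted(dirs)) if dirs else ("none" if len(sub) else "absent")
            else:
                row[col] = "absent"

        if eye is not None:
            cats = eye[eye["homolog"] == hom]["category"]
            row["eye_category"] = ";".join(sorted(set(cats))) if len(cats) else "absent"
        else:
            row["eye_category"] = "absent"

        if cells is not None:
            sub = cells[cells["homolog"] == hom]
            dirs = set(sub["direction"]) - {"none"}
            row["cell_direction"] = ";".join(sorted(dirs)) if dirs else ("none" if len(sub) else "absent")
        else:
            row["cell_direction"] = "absent"

        rows.append(row)

    dossier = pd.DataFrame(rows)
    counts = summarize_counts(dossier)
    # internal consistency: recompute and compare
    assert counts == summarize_counts(dossier)
    return dossier, counts


def _has_wing_phenotype(row) -> bool:
    qual = row["wing_cluster"] not in ("absent", "no_phenotype")
    quant_area = row["area_direction"] not in ("absent", "none")
    quant_l3 = row["L3_direction"] not in ("absent", "none")
    return qual or quant_area or quant_l3


def summarize_counts(dossier: pd.DataFrame) -> dict:
    """Headline counts recomputable from the dossier table.

    Quantitative totals exclude homologs whose every line is lethal; L3
    totals additionally exclude severe homologs.
    """
    n = len(dossier)
    any_wing = int(dossier.apply(_has_wing_phenotype, axis=1).sum())

    def _evaluable(row, exclude) -> bool:
        clusters = set(row["wing_cluster"].split(";"))
        return not clusters <= exclude

    area_rows = dossier[
        (dossier["area_direction"] != "absent")
        & dossier.apply(_evaluable, axis=1, exclude=_QUANT_EXCLUDE)
    ]
    l3_rows = dossier[
        (dossier["L3_direction"] != "absent")
        & dossier.apply(_evaluable, axis=1, exclude=_L3_EXCLUDE)
    ]
    eye_known = dossier[dossier["eye_category"] != "absent"]
    both = eye_known[
        eye_known.apply(_has_wing_phenotype, axis=1)
        & (eye_known["eye_category"] != "no_change")
    ]
    return {
        "n_homologs": n,
        "any_wing_phenotype": any_wing,
        "area_tested": int(len(area_rows)),
        "area_changed": int((area_rows["area_direction"] != "none").sum()),
        "l3_tested": int(len(l3_rows)),
        "l3_changed": int((l3_rows["L3_direction"] != "none").sum()),
        "eye_tested": int(len(eye_known)),
        "eye_and_wing": int(len(both)),
    }


def write_summary(indir, outdir=None) -> tuple[Path, Path]:
    outdir = Path(outdir) if outdir else Path(indir)
    dossier, counts = build_summary(indir)
    tsv = outdir / "summary.tsv"
    js = outdir / "summary.json"
    dossier.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
    with open(js, "w", encoding="utf-8") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv, js
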