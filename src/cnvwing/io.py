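"""Readers and writers for every pipeline table.

All tabular data travel as UTF-8 tab-separated files with a header row;
lines starting with ``#`` are comments.  Gene sets use the GMT convention
(name, description, then members).  Gene identifiers are opaque,
case-sensitive strings.  Parse failures raise :class:`ParseError` carrying
the file, the 1-based line number and the offending field.

Lethal (line, sex) combinations in wing-score files are encoded as a single
row with wing_id ``NA``, phenotype ``lethal`` and severity 5; they carry no
per-wing records.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .config import PHENOTYPES, SEVERITY_LEVELS
from .expression import ExpressionMatrix
from .morphometry import MEASUREMENT_COLUMNS
from .wings import LETHAL_COLUMNS, RECORD_COLUMNS, WingScoreTable

_LETHAL_SENTINEL = "lethal"


class ParseError(ValueError):
    """A malformed input row, locating the file, line and field."""

    def __init__(self, path, line_no: int, field: str, message: str):
        self.path = str(path)
        self.line_no = line_no
        self.field = field
        super().__init__(f"{path}:{line_no}: field {field!r}: {message}")


def _rows(path) -> list[tuple[int, list[str]]]:
    """Non-comment rows of a TSV file with their 1-based line numbers."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#") and len(row) == 1):
                continue
            out.append((i, row))
    return out


def _header(path, rows, expected: list[str]) -> list[tuple[int, list[str]]]:
    if not rows:
        raise ParseError(path, 1, "header", "file is empty")
    line_no, header = rows[0]
    if header != expected:
        raise ParseError(
            path, line_no, "header", f"expected columns {expected}, got {header}"
        )
    return rows[1:]


# ---------------------------------------------------------------------------
# wing scores


def read_wing_scores(path) -> WingScoreTable:
    """Parse a wing-score TSV into records and lethal flags, validating the
    phenotype vocabulary, the severity range, and record uniqueness."""
    rows = _header(path, _rows(path), RECORD_COLUMNS)
    records, lethal, seen = [], [], set()
    for line_no, row in rows:
        if len(row) != len(RECORD_COLUMNS):
            raise ParseError(path, line_no, "row", f"expected {len(RECORD_COLUMNS)} fields")
        line_id, homolog, region, sex, wing_id, phenotype, severity = row
        if phenotype == _LETHAL_SENTINEL:
            lethal.append((line_id, sex, True))
            continue
        if phenotype not in PHENOTYPES:
            raise ParseError(path, line_no, "phenotype", f"unknown phenotype {phenotype!r}")
        try:
            sev = int(severity)
        except ValueError:
            raise ParseError(path, line_no, "severity", f"not an integer: {severity!r}")
        if sev not in SEVERITY_LEVELS:
            raise ParseError(path, line_no, "severity", f"severity {sev} out of range 1-5")
        key = (line_id, sex, wing_id, phenotype)
        if key in seen:
            raise ParseError(path, line_no, "wing_id", f"duplicate record {key}")
        seen.add(key)
        records.append((line_id, homolog, region, sex, wing_id, phenotype, sev))
    if not records and not lethal:
        warnings.warn(f"{path}: no wing records", stacklevel=2)
    table = WingScoreTable(
        records=pd.DataFrame(records, columns=RECORD_COLUMNS),
        lethal=pd.DataFrame(lethal, columns=LETHAL_COLUMNS),
    )
    table.validate()
    return table


def write_wing_scores(table: WingScoreTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for rec in table.records.itertuples(index=False):
            w.writerow(rec)
        for line_id, sex in sorted(table.lethal_keys()):
            w.writerow([line_id, "", "", sex, "NA", _LETHAL_SENTINEL, 5])


# ---------------------------------------------------------------------------
# generic numeric tables


def _read_table(path, columns: list[str], numeric: dict[str, type]) -> pd.DataFrame:
    rows = _header(path, _rows(path), columns)
    parsed = []
    for line_no, row in rows:
        if len(row) != len(columns):
            raise ParseError(path, line_no, "row", f"expected {len(columns)} fields")
        rec = dict(zip(columns, row))
        for col, typ in numeric.items():
            try:
                rec[col] = typ(rec[col])
            except ValueError:
                raise ParseError(path, line_no, col, f"not a {typ.__name__}: {rec[col]!r}")
        parsed.append(rec)
    return pd.DataFrame(parsed, columns=columns)


def _write_table(df: pd.DataFrame, path, columns: list[str]) -> None:
    df[columns].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_measurements(path) -> pd.DataFrame:
    numeric = {m: float for m in MEASUREMENT_COLUMNS[5:]}
    df = _read_table(path, MEASUREMENT_COLUMNS, numeric)
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    _write_table(df, path, MEASUREMENT_COLUMNS)


EYE_COLUMNS = ["line_id", "homolog", "library", "score"]


def read_eye_scores(path) -> pd.DataFrame:
    return _read_table(path, EYE_COLUMNS, {"score": float})


def write_eye_scores(df: pd.DataFrame, path) -> None:
    _write_table(df, path, EYE_COLUMNS)


CELL_COLUMNS = ["line_id", "homolog", "sex", "disc_id", "marker", "count", "censored"]


def read_cell_counts(path) -> pd.DataFrame:
    df = _read_table(path, CELL_COLUMNS, {"count": int})
    df["censored"] = df["censored"].map({"True": True, "False": False})
    if df["censored"].isna().any():
        bad = int(df.index[df["censored"].isna()][0])
        raise ParseError(path, bad + 2, "censored", "must be True or False")
    return df


def write_cell_counts(df: pd.DataFrame, path) -> None:
    _write_table(df, path, CELL_COLUMNS)


# ---------------------------------------------------------------------------
# expression


def read_expression(path) -> ExpressionMatrix:
    """Long-format expression TSV (gene, tissue, value) with ``# unit=`` and
    ``# species=`` comment headers."""
    unit, species = "FPKM", "fly"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.startswith("unit="):
                unit = text.split("=", 1)[1]
            elif text.startswith("species="):
                species = text.split("=", 1)[1]
    df = _read_table(path, ["gene", "tissue", "value"], {"value": float})
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0]
        raise ParseError(path, -1, "value", f"negative value for gene {df.loc[bad, 'gene']!r}")
    wide = df.pivot(index="gene", columns="tissue", values="value")
    if wide.isna().any().any():
        raise ParseError(path, -1, "value", "gene x tissue matrix has missing entries")
    matrix = ExpressionMatrix(values=wide, unit=unit, species=species)
    matrix.validate()
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# unit={matrix.unit}\n# species={matrix.species}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "tissue", "value"])
        for gene in matrix.values.index:
            for tissue in matrix.values.columns:
                w.writerow([gene, tissue, repr(float(matrix.values.loc[gene, tissue]))])


# ---------------------------------------------------------------------------
# networks, gene sets, annotations


def read_edge_list(path) -> pd.DataFrame:
    """Weighted edge list (gene_a, gene_b, posterior): undirected, duplicate
    pairs keep the maximum posterior, self-loops are dropped with a warning."""
    rows = _header(path, _rows(path), ["gene_a", "gene_b", "posterior"])
    best: dict[tuple[str, str], float] = {}
    for line_no, row in rows:
        if len(row) != 3:
            raise ParseError(path, line_no, "row", "expected 3 fields")
        a, b, p_str = row
        try:
            p = float(p_str)
        except ValueError:
            raise ParseError(path, line_no, "posterior", f"not a float: {p_str!r}")
        if not 0.0 <= p <= 1.0:
            raise ParseError(path, line_no, "posterior", f"probability {p} outside [0, 1]")
        if a == b:
            warnings.warn(f"{path}:{line_no}: self-loop on {a!r} dropped", stacklevel=2)
            continue
        key = (min(a, b), max(a, b))
        best[key] = max(p, best.get(key, 0.0))
    return pd.DataFrame(
        [(a, b, p) for (a, b), p in sorted(best.items())],
        columns=["gene_a", "gene_b", "posterior"],
    )


def write_edge_list(edges: pd.DataFrame, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b", "posterior"])
        for a, b, p in edges[["gene_a", "gene_b", "posterior"]].itertuples(index=False):
            w.writerow([a, b, repr(float(p))])


def read_gene_sets(path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, then members (deduplicated,
    first-occurrence order).  Set names must be unique."""
    sets: dict[str, list[str]] = {}
    for line_no, row in _rows(path):
        if len(row) < 3:
            raise ParseError(path, line_no, "row", "GMT rows need name, description and >=1 gene")
        name, _desc, *genes = row
        genes = [g for g in genes if g]
        if not genes:
            raise ParseError(path, line_no, "genes", f"gene set {name!r} is empty")
        if name in sets:
            raise ParseError(path, line_no, "name", f"duplicate gene set {name!r}")
        sets[name] = list(dict.fromkeys(genes))
    if not sets:
        raise ParseError(path, 1, "file", "no gene sets found")
    return sets


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for name, genes in sets.items():
            w.writerow([name, "", *genes])


def read_annotations(path) -> dict[str, set]:
    """Gene-to-term table (gene, term) into a gene -> set-of-terms map."""
    rows = _header(path, _rows(path), ["gene", "term"])
    out: dict[str, set] = {}
    for line_no, row in rows:
        if len(row) != 2:
            raise ParseError(path, line_no, "row", "expected 2 fields")
        gene, term = row
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: dict[str, set], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "term"])
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                w.writerow([gene, term])


# ---------------------------------------------------------------------------
# config


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(path, 1, "document", "config must be a YAML mapping")
    return data


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
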