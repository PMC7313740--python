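"""Qualitative wing-phenotype analysis.

Per-wing ordinal severity scores (five phenotypes, levels 1-4 per wing,
level 5 reserved for line-level lethality) are turned into per-line
frequency matrices, clustered into severity classes by k-means, and tested
for sex differences in phenotype prevalence with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .config import PHENOTYPES, SEVERITY_CLASSES, SEVERITY_LEVELS
from .stats import FisherResult, fisher_2x2

#: Human-readable cluster labels, ascending in severity.
CLUSTER_LABELS: tuple[str, ...] = SEVERITY_CLASSES

RECORD_COLUMNS = ["line_id", "homolog", "region", "sex", "wing_id", "phenotype", "severity"]
LETHAL_COLUMNS = ["line_id", "sex", "lethal"]


@dataclass
class WingScoreTable:
    """Per-wing severity records plus per-(line, sex) lethal flags.

    ``records`` columns: line_id, homolog, region, sex (F/M), wing_id,
    phenotype, severity (1-4).  Lethal (line, sex) combinations carry no
    wing records; they are listed in ``lethal`` with lethal=True.
    """

    records: pd.DataFrame
    lethal: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LETHAL_COLUMNS)
    )

    def validate(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"wing score records missing columns: {sorted(missing)}")
        bad_ph = set(self.records["phenotype"]) - set(PHENOTYPES)
        if bad_ph:
            raise ValueError(f"unknown phenotypes: {sorted(bad_ph)}")
        sev = self.records["severity"]
        if len(sev) and not sev.isin(SEVERITY_LEVELS).all():
            bad = sorted(set(sev) - set(SEVERITY_LEVELS))
            raise ValueError(f"severities out of range: {bad}")
        dup = self.records.duplicated(["line_id", "sex", "wing_id", "phenotype"])
        if dup.any():
            raise ValueError(
                f"duplicate (line, sex, wing, phenotype) records at rows "
                f"{list(self.records.index[dup][:5])}"
            )
        lethal_keys = self.lethal_keys()
        if lethal_keys:
            rec_keys = set(zip(self.records["line_id"], self.records["sex"]))
            overlap = lethal_keys & rec_keys
            if overlap:
                raise ValueError(
                    f"lethal (line, sex) combinations carry wing records: {sorted(overlap)[:5]}"
                )

    def lethal_keys(self) -> set[tuple[str, str]]:
        if self.lethal.empty:
            return set()
        flagged = self.lethal[self.lethal["lethal"].astype(bool)]
        return set(zip(flagged["line_id"], flagged["sex"]))


def apply_severity_override(table: WingScoreTable) -> WingScoreTable:
    """Propagate severe wrinkling: a wing scored 4 for wrinkled wings is
    scored 4 for all five phenotypes.  Lethality is already line-level and
    needs no per-wing change."""
    rec = table.records.copy()
    if not rec.empty:
        wr = rec[(rec["phenotype"] == "wrinkled") & (rec["severity"] == 4)]
        keys = set(zip(wr["line_id"], wr["sex"], wr["wing_id"]))
        if keys:
            mask = [
                (l, s, w) in keys
                for l, s, w in zip(rec["line_id"], rec["sex"], rec["wing_id"])
            ]
            rec.loc[mask, "severity"] = 4
    return WingScoreTable(records=rec, lethal=table.lethal.copy())


def frequency_columns() -> list[str]:
    return [f"{ph}_s{lvl}" for ph in PHENOTYPES for lvl in SEVERITY_LEVELS]


def score_frequencies(table: WingScoreTable) -> pd.DataFrame:
    """Per-(line, sex) frequency of each severity level for each phenotype.

    Returns a frame indexed by (line_id, sex) with 25 frequency columns
    (``<phenotype>_s<level>``) plus ``n_wings``.  Lethal rows are degenerate:
    frequency 1 at level 5 for every phenotype, n_wings = 0.
    """
    table.validate()
    rows: dict[tuple[str, str], np.ndarray] = {}
    n_wings: dict[tuple[str, str], int] = {}

    if not table.records.empty:
        grouped = table.records.groupby(["line_id", "sex"], sort=True)
        for (line, sex), sub in grouped:
            wings = sub["wing_id"].nunique()
            freq = np.zeros((len(PHENOTYPES), len(SEVERITY_LEVELS)))
            counts = sub.groupby(["phenotype", "severity"]).size()
            for (ph, lvl), c in counts.items():
                freq[PHENOTYPES.index(ph), SEVERITY_LEVELS.index(lvl)] = c / wings
            rows[(line, sex)] = freq.ravel()
            n_wings[(line, sex)] = wings

    for key in sorted(table.lethal_keys()):
        freq = np.zeros((len(PHENOTYPES), len(SEVERITY_LEVELS)))
        freq[:, SEVERITY_LEVELS.index(5)] = 1.0
        rows[key] = freq.ravel()
        n_wings[key] = 0

    if not rows:
        raise ValueError("no wing records and no lethal lines: nothing to summarize")

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["line_id", "sex"])
    out = pd.DataFrame(
        [rows[k] for k in index], index=index, columns=frequency_columns()
    )
    # guard: each phenotype's five frequencies sum to 1 per row
    for ph in PHENOTYPES:
        cols = [f"{ph}_s{lvl}" for lvl in SEVERITY_LEVELS]
        if not np.allclose(out[cols].sum(axis=1), 1.0):
            raise AssertionError(f"frequencies for {ph} do not sum to 1")
    out["n_wings"] = [n_wings[k] for k in index]
    return out


def severity_index(freqs: pd.DataFrame) -> pd.Series:
    """Severity index S = sum over phenotypes and levels of (level-1)*frequency.

    Ranges 0 (all wings unaffected) to 20 (lethal)."""
    s = pd.Series(0.0, index=freqs.index)
    for ph in PHENOTYPES:
        for lvl in SEVERITY_LEVELS:
            s = s + (lvl - 1) * freqs[f"{ph}_s{lvl}"]
    return s


@dataclass
class SeverityClusterResult:
    assignments: pd.DataFrame   # index line_id; columns cluster, label, severity_index
    cluster_sizes: dict[str, int]
    inertia: float


def cluster_severity(
    freqs: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    restarts: int = 100,
    sex: str = "F",
) -> SeverityClusterResult:
    """k-means clustering of per-line severity frequency profiles for one sex.

    Euclidean k-means on the 25 frequency columns (k-means++ seeding, best of
    ``restarts`` runs by within-cluster sum of squares).  Clusters are then
    labeled in ascending order of their mean severity index, so labels are
    comparable across runs regardless of the arbitrary k-means indices.
    """
    cols = frequency_columns()
    sub = freqs.xs(sex, level="sex")[cols] if "sex" in (freqs.index.names or []) else freqs[cols]
    if len(sub) < k:
        raise ValueError(f"need at least k={k} rows, got {len(sub)}")
    n_distinct = len(sub.drop_duplicates())
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct profiles for k={k}; clusters will be "
            "degenerate",
            stacklevel=2,
        )
    X = sub.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    s_index = severity_index(freqs.xs(sex, level="sex") if "sex" in (freqs.index.names or []) else freqs)

    # order cluster indices by ascending mean severity index
    mean_s = pd.Series(s_index.to_numpy(), index=sub.index).groupby(km.labels_).mean()
    order = mean_s.sort_values(kind="stable").index.to_list()
    labels = CLUSTER_LABELS if k == len(CLUSTER_LABELS) else tuple(
        f"cluster_{i}" for i in range(k)
    )
    relabel = {old: labels[rank] for rank, old in enumerate(order)}

    assignments = pd.DataFrame(
        {
            "cluster": [order.index(c) for c in km.labels_],
            "label": [relabel[c] for c in km.labels_],
            "severity_index": s_index.to_numpy(),
        },
        index=sub.index,
    )
    sizes = assignments["label"].value_counts().to_dict()
    return SeverityClusterResult(
        assignments=assignments,
        cluster_sizes={lab: int(sizes.get(lab, 0)) for lab in labels},
        inertia=float(km.inertia_),
    )


def phenotype_presence(
    table: WingScoreTable, phenotype: str, min_severity: int = 2
) -> pd.DataFrame:
    """Line-level presence of one phenotype per sex.

    A (line, sex) shows the phenotype when at least one wing scores
    >= ``min_severity`` for it; lethal (line, sex) combinations count as
    present."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rec = table.records
    present: dict[tuple[str, str], bool] = {}
    if not rec.empty:
        sub = rec[rec["phenotype"] == phenotype]
        for (line, sex), g in sub.groupby(["line_id", "sex"]):
            present[(line, sex)] = bool((g["severity"] >= min_severity).any())
    for key in table.lethal_keys():
        present[key] = True
    if not present:
        return pd.DataFrame(columns=["line_id", "sex", "present"])
    return pd.DataFrame(
        [(l, s, p) for (l, s), p in sorted(present.items())],
        columns=["line_id", "sex", "present"],
    )


def sex_phenotype_test(
    table: WingScoreTable, phenotype: str, min_severity: int = 2
) -> FisherResult:
    """Two-tailed Fisher's exact test of male vs female phenotype prevalence.

    Counts lines with/without the phenotype per sex over all lines scored in
    both sexes (lethality counts as scored and present); the 2x2 table is
    (males with, males without) x (females with, females without).
    """
    pres = phenotype_presence(table, phenotype, min_severity)
    if pres.empty:
        warnings.warn("no lines scored; Fisher p set to 1", stacklevel=2)
        return FisherResult(table=((0, 0), (0, 0)), odds_ratio=float("nan"), p=1.0)
    wide = pres.pivot(index="line_id", columns="sex", values="present")
    both = wide.dropna(subset=[c for c in ("F", "M") if c in wide.columns])
    if "F" not in both.columns or "M" not in both.columns or both.empty:
        warnings.warn("phenotype not scored in both sexes; Fisher p set to 1", stacklevel=2)
        return FisherResult(table=((0, 0), (0, 0)), odds_ratio=float("nan"), p=1.0)
    m_with = int(both["M"].sum())
    f_with = int(both["F"].sum())
    n = len(both)
    return fisher_2x2([[m_with, n - m_with], [f_with, n - f_with]])
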