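"""Synthetic screen generator with known ground truth.

Every pipeline input can be generated here so the full analysis is testable
without any external download: multinomial per-wing severity draws per RNAi
line, normally distributed wing measurements with line-specific
multiplicative effects, lognormal eye scores, Poisson disc cell counts,
expression matrices with planted preferential tissues, and random tissue
networks with Beta-distributed edge posteriors, planted high-probability
shortest paths, and a term-enriched connector annotation table.

Each generator draws from its own pseudo-random stream derived from
(master seed, generator name), so adding or re-running one generator never
changes another's output, and a fixed config+seed reproduces every table
byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import (
    PHENOTYPES,
    SEVERITY_LEVELS,
    ConfigurationError,
    SimulationConfig,
)
from .expression import ExpressionMatrix, preferential_tissues
from .network import shortest_path, threshold_network
from .wings import LETHAL_COLUMNS, RECORD_COLUMNS, WingScoreTable

#: CNV regions cycled through when labeling synthetic lines.
_REGIONS = (
    "1q21.1", "3q29", "7q11.23", "15q11.2", "15q13.3",
    "16p11.2", "distal_16p11.2", "16p12.1", "16p13.11", "17q12",
)


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one generator under one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed) % 2**31, zlib.crc32(name.encode())))
    )


def _homolog_for(line: str) -> str:
    """Consistent homolog name for a synthetic line across all generators."""
    if line.startswith("line_") and line[5:].isdigit():
        return f"gene_{line[5:]}"
    return f"g_{line}"


# ---------------------------------------------------------------------------
# wing scores


def gen_wing_scores(config: SimulationConfig) -> tuple[WingScoreTable, dict[str, str]]:
    """Per-wing severity records for every line, plus the true class map.

    Lines are laid out class by class in the order of ``class_sizes``.
    Lethal lines produce no wing records and a lethal flag in both sexes;
    all other lines get ``n_wings_per_line`` wings per sex, each wing scored
    once per phenotype from the class's multinomial.
    """
    config.validate()
    rng = stream(config.seed, "wing_scores")
    records: list[tuple] = []
    lethal: list[tuple] = []
    truth: dict[str, str] = {}
    line_no = 0
    for cls, n_lines in config.class_sizes.items():
        profiles = config.severity_profiles.get(cls)
        if profiles is None and cls != "lethal" and n_lines > 0:
            raise ConfigurationError(f"no severity profile for class {cls!r}")
        for _ in range(n_lines):
            line = f"line_{line_no:03d}"
            homolog = f"gene_{line_no:03d}"
            region = _REGIONS[line_no % len(_REGIONS)]
            truth[line] = cls
            if cls == "lethal":
                for sex in ("F", "M"):
                    lethal.append((line, sex, True))
            else:
                for sex in ("F", "M"):
                    for w in range(config.n_wings_per_line):
                        wing = f"w{w:02d}"
                        for ph in PHENOTYPES:
                            p = np.asarray(profiles[ph], dtype=float)
                            sev = int(rng.choice(SEVERITY_LEVELS, p=p))
                            records.append(
                                (line, homolog, region, sex, wing, ph, sev)
                            )
            line_no += 1
    table = WingScoreTable(
        records=pd.DataFrame(records, columns=RECORD_COLUMNS),
        lethal=pd.DataFrame(lethal, columns=LETHAL_COLUMNS),
    )
    table.validate()
    return table, truth


# ---------------------------------------------------------------------------
# measurements

#: Baseline wing morphometry (means, um^2 for area and um for veins) with a
#: common 5% coefficient of variation.
_BASELINES = {
    "area": 1.7e6, "L2": 1400.0, "L3": 1700.0, "L4": 1600.0,
    "L5": 1200.0, "ACV": 250.0, "PCV": 350.0,
}
_CV = 0.05


def gen_measurements(config: SimulationConfig) -> pd.DataFrame:
    """Wing area and vein lengths for effect lines and matched controls.

    Controls (one per library) draw from baseline normals; each line in
    ``measurement_effects`` draws from the baseline scaled by its
    multiplicative effect.  Values are truncated away from zero so all
    measurements stay positive.
    """
    config.validate()
    rng = stream(config.seed, "measurements")
    n = config.n_wings_measured
    rows = []

    def sample_group(line_id, homolog, library, effect):
        for sex in ("F", "M"):
            for w in range(n):
                vals = {}
                for m, mu in _BASELINES.items():
                    loc = mu * effect
                    v = rng.normal(loc, _CV * loc)
                    vals[m] = max(v, 0.05 * loc)
                rows.append(
                    {"line_id": line_id, "homolog": homolog, "library": library,
                     "sex": sex, "wing_id": f"w{w:02d}", **vals}
                )

    for lib in ("GD", "KK"):
        sample_group(f"control_{lib}", "control", f"control_{lib}", 1.0)
    for i, (line, effect) in enumerate(sorted(config.measurement_effects.items())):
        lib = ("GD", "KK")[i % 2]
        sample_group(line, _homolog_for(line), lib, effect)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eye scores


def gen_eye_scores(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lognormal per-fly eye scores around true fold change x control median.

    Returns (line scores, control scores); control flies number the top of
    the per-line n range.  Per-line n is drawn uniformly from
    ``eye_n_range``.
    """
    config.validate()
    rng = stream(config.seed, "eye_scores")
    lo, hi = config.eye_n_range
    sigma = config.eye_sigma
    base = config.eye_control_median
    # lognormal with median exp(mu): set mu = log(target median)
    controls = pd.DataFrame(
        {
            "line_id": "control",
            "homolog": "control",
            "library": "GD",
            "score": rng.lognormal(np.log(base), sigma, size=hi),
        }
    )
    rows = []
    for line, fc in sorted(config.eye_fc_effects.items()):
        if fc < 0:
            raise ConfigurationError(f"eye fold change for {line!r} must be >= 0")
        n = int(rng.integers(lo, hi + 1))
        scores = rng.lognormal(np.log(base * max(fc, 1e-12)), sigma, size=n)
        for s in scores:
            rows.append(
                {"line_id": line, "homolog": _homolog_for(line), "library": "GD",
                 "score": s}
            )
    return pd.DataFrame(rows, columns=["line_id", "homolog", "library", "score"]), controls


# ---------------------------------------------------------------------------
# cell counts


def gen_cell_counts(config: SimulationConfig) -> pd.DataFrame:
    """Poisson per-disc marker counts for effect lines and a control group.

    Control discs draw at ``cell_control_rate``; each line in
    ``cell_rate_ratios`` draws at ratio x control rate.  Both sexes and both
    markers are generated; per-line disc n is uniform on ``cell_n_range``.
    """
    config.validate()
    rng = stream(config.seed, "cell_counts")
    lo, hi = config.cell_n_range
    rows = []

    def sample_group(line_id, homolog, ratio):
        for marker in ("pH3", "dcp1"):
            for sex in ("F", "M"):
                n = int(rng.integers(lo, hi + 1))
                counts = rng.poisson(config.cell_control_rate * ratio, size=n)
                for d, c in enumerate(counts):
                    rows.append(
                        {"line_id": line_id, "homolog": homolog, "sex": sex,
                         "disc_id": f"d{d:02d}", "marker": marker,
                         "count": int(c), "censored": False}
                    )

    sample_group("control", "control", 1.0)
    for line, ratio in sorted(config.cell_rate_ratios.items()):
        sample_group(line, _homolog_for(line), ratio)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression


def gen_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Expression matrix with planted preferential tissues.

    Non-planted rows are rejection-sampled until no tissue passes the
    Q3 + 1.5*IQR outlier rule, so the planted truth is exactly the set of
    flagged (gene, tissue) pairs.  Planted rows get one tissue inflated
    until the rule flags exactly that tissue.
    """
    config.validate()
    if config.n_tissues < 3:
        raise ConfigurationError("need at least 3 tissues")
    rng = stream(config.seed, "expression")
    genes = [f"gene_{i:03d}" for i in range(config.n_genes)]
    tissues = [f"tissue_{j}" for j in range(config.n_tissues)]
    n_pref = int(round(config.preferential_fraction * config.n_genes))
    pref_genes = list(rng.choice(config.n_genes, size=n_pref, replace=False)) if n_pref else []

    def quiet_row() -> np.ndarray:
        # a row with no natural outlier under the preferential rule
        for _ in range(1000):
            base = rng.lognormal(np.log(50.0), 0.8)
            row = base * rng.lognormal(0.0, 0.35, size=config.n_tissues)
            if not preferential_tissues(pd.Series(row, index=tissues)):
                return row
        raise RuntimeError("could not draw an outlier-free expression row")

    values = np.empty((config.n_genes, config.n_tissues))
    truth: dict[str, list[str]] = {}
    for i in range(config.n_genes):
        row = quiet_row()
        if i in pref_genes:
            j = int(rng.integers(config.n_tissues))
            v = float(row.max()) * 1.5 + 1.0
            for _ in range(200):
                cand = row.copy()
                cand[j] = v
                flagged = preferential_tissues(pd.Series(cand, index=tissues))
                if flagged == [tissues[j]]:
                    row = cand
                    break
                v *= 2.0
            else:
                raise RuntimeError("failed to plant a preferential tissue")
            truth[genes[i]] = [tissues[j]]
        values[i] = row
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=tissues),
        unit=config.expression_unit,
        species=config.expression_species,
    )
    matrix.validate()
    return matrix, truth


# ---------------------------------------------------------------------------
# network


@dataclass
class SyntheticNetwork:
    """One synthetic tissue network with its complete ground truth."""

    edges: pd.DataFrame                      # gene_a, gene_b, posterior
    cnv_genes: list[str]
    pathway_sets: dict[str, list[str]] = field(default_factory=dict)
    annotations: dict[str, set] = field(default_factory=dict)
    planted_paths: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    enriched_term: str = ""

    @property
    def planted_connectors(self) -> dict[tuple[str, str], list[str]]:
        return {k: v[1:-1] for k, v in self.planted_paths.items()}


def gen_network(config: SimulationConfig) -> SyntheticNetwork:
    """Random tissue network with planted unique shortest paths.

    Background edges are Erdos-Renyi with Beta posteriors capped below the
    planted posterior; planted path edges get the high planted posterior.
    Background edges that would beat a planted route (including direct
    source-target edges) are removed in a repair pass, guaranteeing each
    planted route is the unique weighted shortest path for its endpoint
    pair.  Connector genes on planted paths are annotated with one enriched
    term at the planted rate; all genes carry background annotations.
    """
    config.validate()
    np_ = config.network_params
    gp = config.go_params
    rng = stream(config.seed, "network")
    nodes = [f"g{i:03d}" for i in range(np_.n_nodes)]
    order = list(rng.permutation(np_.n_nodes))

    # carve out planted paths from a random node ordering
    planted_paths: dict[tuple[str, str], list[str]] = {}
    used = 0
    for _ in range(np_.n_planted_paths):
        chunk = [nodes[order[used + j]] for j in range(2 + np_.n_connectors_per_path)]
        used += 2 + np_.n_connectors_per_path
        planted_paths[(chunk[0], chunk[-1])] = chunk

    planted_edges: dict[tuple[str, str], float] = {}
    for path in planted_paths.values():
        for a, b in zip(path, path[1:]):
            key = (min(a, b), max(a, b))
            planted_edges[key] = np_.planted_posterior

    endpoint_pairs = {(min(s, t), max(s, t)) for s, t in planted_paths}
    background: dict[tuple[str, str], float] = {}
    cap = min(0.9 * np_.planted_posterior, 0.6)
    for i in range(np_.n_nodes):
        for j in range(i + 1, np_.n_nodes):
            if rng.random() < np_.edge_prob:
                key = (nodes[i], nodes[j])
                if key in planted_edges or key in endpoint_pairs:
                    continue
                background[key] = float(min(rng.beta(np_.beta_a, np_.beta_b), cap))

    def build_edges() -> pd.DataFrame:
        items = sorted({**background, **planted_edges}.items())
        return pd.DataFrame(
            [(a, b, p) for (a, b), p in items],
            columns=["gene_a", "gene_b", "posterior"],
        )

    # repair pass: delete background edges that beat a planted route
    for _ in range(50):
        g = threshold_network(build_edges(), p_min=0.0)
        clean = True
        for (s, t), path in planted_paths.items():
            r = shortest_path(g, s, t)
            if r.path != path:
                clean = False
                for a, b in zip(r.path, r.path[1:]):
                    key = (min(a, b), max(a, b))
                    if key in background:
                        del background[key]
                        break
                else:
                    raise RuntimeError("planted path beaten by other planted edges")
        if clean:
            break
    else:
        raise RuntimeError("could not make planted paths uniquely shortest")

    connectors = sorted({c for p in planted_paths.values() for c in p[1:-1]})
    terms = [f"GO:{i + 1:07d}" for i in range(gp.n_terms)]
    enriched = terms[0]
    annotations: dict[str, set] = {}
    for n in nodes:
        terms_n = {t for t in terms[1:] if rng.random() < gp.background_rate}
        rate = gp.planted_rate if n in connectors else gp.background_rate
        if rng.random() < rate:
            terms_n.add(enriched)
        annotations[n] = terms_n

    cnv_genes = sorted({s for s, _ in planted_paths})
    targets = sorted({t for _, t in planted_paths})
    spare = [n for n in nodes if n not in cnv_genes and n not in targets and n not in connectors]
    extra = [spare[i] for i in range(min(5, len(spare)))]
    pathway_sets = {
        "planted_pathway": sorted(targets + extra[:2]),
        "background_pathway": sorted(extra[2:]),
    }
    return SyntheticNetwork(
        edges=build_edges(),
        cnv_genes=cnv_genes,
        pathway_sets=pathway_sets,
        annotations=annotations,
        planted_paths=planted_paths,
        enriched_term=enriched,
    )
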