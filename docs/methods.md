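# Methods

`cnvwing` re-implements, as a reusable and tested pipeline, the quantitative
analysis of a genome-wide Drosophila RNAi screen in which fly homologs of
human copy-number-variant (CNV) and neurodevelopmental genes are knocked
down tissue-specifically and the resulting wing, eye and cellular phenotypes
are quantified. This note documents the models, the fixed constants, the
numerical conventions, and the design decisions taken where the procedure
was genuinely open.

## Qualitative wing severity

Each adult wing is scored for five phenotypes (wrinkled wing, discoloration,
ectopic veins, missing veins, bristle planar polarity) on an ordinal scale
where 1 means no phenotype and 4 severe; 5 is a line-level terminal category
(lethality), not a per-wing observation. Two fixed rules shape the data
before any statistics:

- **Severe-wrinkling override.** A wing whose wrinkled-wing score is 4 is
  scored 4 for all five phenotypes: heavy wrinkling physically obscures the
  other traits, so partial scores on such wings are not comparable.
- **Lethal degeneracy.** A lethal (line, sex) combination contributes no
  wings; its frequency row is defined as probability 1 at level 5 for every
  phenotype.

Per (line, sex), the frequency of each severity level for each phenotype is
computed over that line's wings (20–25 per sex in the screen; the generator
defaults to 22), yielding a 25-dimensional profile per line. Female
profiles are clustered with Euclidean k-means (k = 5, k-means++ seeding,
best of 100 restarts by within-cluster sum of squares; scikit-learn).
Cluster indices are arbitrary, so clusters are relabeled in ascending order
of their mean severity index

S = Σ_phenotype Σ_level (level − 1) · frequency,  S ∈ [0, 20],

giving the ordered labels {no phenotype, mild, moderate, severe, lethal}.
The 25 frequency columns are used unstandardized — they already live on
[0, 1] and the level-1 column, though redundant, keeps the matrix
self-describing. k is fixed at 5 because the severity vocabulary has five
ordered categories; no model-selection procedure is applied.

**Sex contrasts.** A line "shows" a phenotype when at least one wing scores
≥ 2 for it (lethal lines count as present). Male versus female prevalence
over lines scored in both sexes is tested with a two-tailed Fisher exact
test (two-sided p = sum of probabilities of tables no more likely than the
observed one, at fixed margins). The line-level presence threshold is a
package decision: the screen publication defines no line-level presence
rule. Of note, the prevalence counts printed in that literature (87 vs 55
discoloration lines, 92 vs 29 missing-vein lines, out of 136 per sex) do
not reproduce the p-values printed next to them under any standard Fisher
convention we tried; the package reports the p-values its own test
computes from the printed counts.

## Wing morphometry

Total wing area and six vein lengths (longitudinal L2–L5, anterior and
posterior crossveins) are compared per line against the control matched by
RNAi library (GD vs KK) and sex with a two-tailed Mann–Whitney test.
The U statistic uses midranks for ties; p is exact (full enumeration) when
the pooled sample is tie-free with n ≤ 12, otherwise the normal
approximation with tie and continuity correction is used. All line × measure
tests within one sex form one Benjamini–Hochberg family, mirroring
per-experiment correction; a direction (smaller/larger) is assigned from
the median ratio when the adjusted q < 0.05. Medians rather than means
drive the direction call, consistent with the rank-based test.

**Homolog aggregation and discordance.** A line's verdict collapses its
qualitative cluster label and quantitative directions (severity order:
lethal > severe > moderate > mild > size-defect-only > none); a homolog's
verdict is its most severe line verdict. A homolog is flagged discordant
when (a) one line shows no phenotype of any kind while another shows any,
or else (b) its lines disagree on the direction of a size change.

## Eye phenotypes

Per-fly ommatidial-disorganization scores (an image-derived scalar; the
scoring algorithm itself is external to this package) are normalized as
fold change FC = score / median(control). Line severity uses the median FC
with fixed boundaries: [0, 1.1] no change, (1.1, 1.5] mild, (1.5, 2.0]
moderate, (2.0, ∞) severe. The printed category ranges overlap at their
endpoints; the closed-right convention (1.1 → no change, 1.5 → mild,
2.0 → moderate) was chosen and is tested. Each line is tested against
control with a one-tailed (greater) Mann–Whitney test, BH-corrected across
lines.

**Eye/wing concordance.** Per-line average FC (mean across flies; the
median is also reported) is compared across six wing categories — the five
severity clusters with "no phenotype" split into no-defect and
size-defect-only — with a tie-corrected Kruskal–Wallis test (df = groups −
1, six groups giving df = 5) and post-hoc pairwise Wilcoxon tests with BH
correction. Empty categories are dropped with a warning, reducing df.

## Cellular assays

Proliferation (pH3) and apoptosis (dcp1) counts per larval wing disc are
normalized to the control median and tested per line with two-tailed
Mann–Whitney tests, BH-corrected within one marker. Discs whose staining
covers the whole disc cannot be counted; they are carried as censored,
excluded from the test and from n, and reported alongside. Sex-stratified
analysis tests each sex against its matched control and flags a line
sex-discordant for a marker when exactly one sex reaches significance.

## Tissue expression

Expression matrices are gene × tissue with species-specific units and bin
edges: fly FPKM at 10/100/500/1000 and human TPM at 3/10/25/100, both
left-closed right-open (a value exactly at an edge falls in the higher
bin), mapping to {none, low, moderate, high, very high}. Sub-tissues
(e.g. midgut/hindgut/Malpighian tube → gut; brain sub-regions → brain) are
aggregated by median on raw values *before* binning — binning does not
commute with the median, so aggregate-then-bin is the canonical order.

A tissue is **preferentially expressed** for a gene when its value strictly
exceeds Q3 + 1.5·IQR of that gene's values across all tissues, with
quartiles by linear interpolation at rank q·(n−1). The strict inequality
means constant rows never flag; the rule is scale-equivariant but not
shift-invariant. The quantile convention is a package decision (the most
common analytic default) — borderline tissues can flip under other
conventions.

Summary counts report genes expressed (category ≠ none) in ≥ 1 tissue, in
all tissues, in ≥ 1 non-neuronal tissue, and in no neuronal tissue, with
the neuronal tissue set declared per species (fly: larval CNS/adult brain;
human: brain).

## Network connectivity

Tissue-specific probabilistic gene networks arrive as weighted edge lists
(posterior probability that two genes functionally interact in that
tissue). Edges with posterior strictly greater than 0.2 are retained —
roughly the top 0.5% of interactions in networks of this kind — and each
edge gets traversal weight w = 1/posterior, so confident interactions are
short. For every (CNV gene, pathway gene) pair, Dijkstra's algorithm
(networkx) gives the weighted shortest path; **connectivity** is 1/length,
which for an adjacent pair whose direct edge is optimal equals the edge
posterior. Connectivity values lie in (0, 1]; unreachable pairs get
connectivity 0 and are excluded from downstream comparisons.

Among tied shortest paths the canonical path is the lexicographically
smallest node sequence — a deterministic tie-break so connector extraction
is reproducible; `connectors="union"` collects interior nodes of all tied
paths instead. Genes appearing in both the CNV set and a pathway set are
skipped (zero-distance degenerate pairs), and pair universes are computed
per tissue because node sets differ between tissue networks.

Connectivity distributions are compared between tissues within each
pathway with two-tailed Welch t-tests (unequal variances,
Welch–Satterthwaite df), BH-corrected across all comparisons in a run.
Connector sets are tested for annotation-term over-representation with
one-tailed Fisher exact tests against the annotated nodes of that tissue's
network as background (an external tool's default background would not be
reproducible), BH-corrected across terms.

## Synthetic screen generator

Every pipeline input can be generated with known ground truth:

- **Wing scores**: per-class multinomials over severity levels, one per
  phenotype; class composition defaults to the screen's 136 lines split
  75/24/10/21/6 across the five classes; lethal lines produce no wings and
  a lethal flag. The default class profiles are well separated so that
  clustering recovery is a meaningful end-to-end check.
- **Measurements**: baseline normals (area 1.7·10⁶ µm², vein lengths
  250–1700 µm, 5% CV) scaled per line by a multiplicative effect.
- **Eye scores**: lognormal per fly around true FC × control median
  (control median 30, shape σ = 0.25; per-line n uniform on 7–40).
- **Cell counts**: Poisson per disc at control rate 30 times the line's
  rate ratio (per-line n uniform on 6–18).
- **Expression**: lognormal rows; non-planted rows are rejection-sampled
  until no tissue passes the outlier rule, and planted rows have one tissue
  inflated until exactly that tissue passes — so the planted truth is
  recovered exactly, by construction.
- **Networks**: Erdős–Rényi background with Beta(1.2, 4) posteriors capped
  below the planted level; planted paths get posterior 0.95 and a repair
  pass removes any background edge that would beat a planted route, making
  each planted route the unique weighted shortest path. Connector genes on
  planted paths carry one enriched annotation term at rate 0.8 against a
  background rate of 0.1.

Each generator draws from an independent stream derived from (master seed,
generator name), so outputs are byte-reproducible and adding a generator
never perturbs the others.

What the generator does *not* emulate: inter-rater scoring noise,
batch/temperature effects across crosses, X-linked dosage-compensation
mechanisms behind male/female differences (sex effects enter only through
user-specified parameters), correlated phenotypes within a wing beyond the
override rule, scale-free topology of real interaction networks, and
probe-level expression noise. Green tests on synthetic data therefore
certify the statistical machinery and the recovery of planted structure,
not the biology of any particular screen.

## Numerical conventions and degenerate inputs

- Identical constant samples: Mann–Whitney and Welch return p = 1; an
  all-equal Kruskal–Wallis returns H = 0, p = 1; an empty 2×2 margin
  returns p = 1 with a warning. This keeps BH families well formed.
- Shortest-path tie detection uses a relative tolerance of 1e-9 on path
  lengths.
- BH adjustment is the step-up map q_(i) = min_{j≥i} p_(j)·m/j capped at 1.
  It is monotone and dominates p but is *not* idempotent as a map; the
  tested invariants are the hand-computed step-up values, monotonicity,
  q ≥ p, and fixed-point stability.
- k-means with fewer distinct profiles than k warns and reports degenerate
  clusters; fewer rows than k is an error.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at deliberately modest sizes chosen as the package's own verification
scale: screen-scale clustering at 136 lines, operating characteristics
over 400–1000 null seeds (null rejection ≈ 0.05, half-effect power ≈ 1 at
n = 20 wings/group), Monte-Carlo detection rates over 60–200 seeds,
brute-force shortest-path cross-checks on 500 random graphs of ≤ 8 nodes,
and exact-enumeration cross-checks of Mann–Whitney (pooled n ≤ 12) and
Fisher/enrichment p-values (backgrounds ≤ 30). Reproductions that require
the original study's per-line supplementary tables are expressed as tests
that read TSV conversions from `data/supplementary/`; without those files
they fail with an explanatory message rather than silently passing.
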