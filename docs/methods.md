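# Methods

This note documents the models, parameter choices and numerical rules
implemented in `acecontact`, the assumptions behind them, and what the
synthetic benchmarks do and do not demonstrate.

## The enhancement model

The working hypothesis is that a fold-switching protein's superfamily
alignment mixes two populations: a majority of single-fold homologs whose
covariation supports one ("dominant") conformation, and a query-similar
subfamily whose sequences also covary at residue pairs unique to the
alternative conformation. Coevolution inference on the whole superfamily
averages over both populations, so the minority signal is diluted below the
retention threshold. Pruning the alignment by identity to the query (QID)
progressively enriches the subfamily; running inference on every pruned
alignment and pooling the results lets couplings that are strong *in any
stratum* survive.

Key consequences built into the code:

- **Absence-aware averaging.** In the superposition, a pair's mean z-score
  is taken only over runs that retained it. Zero-filling absent runs would
  re-impose exactly the dilution the method exists to undo.
- **Per-run retention before pooling.** Each (alignment, method) run keeps
  its top `3L/2` pairs; the pooled map keeps the top `15L/2` by mean
  z-score. Ties break deterministically (higher support, then lower `i`,
  then lower `j`).
- **Per-run z-scoring** (population standard deviation over the run's own
  pairs) makes runs from alignments of very different depths comparable.
  Whether multiple inference methods should instead be standardized jointly
  is untested; per-run scoring is the default and only mode.

## Alignment handling

- QID is the fraction of columns, among those where the query is non-gap,
  where a row matches the query residue. Columns where the query is gapped
  are excluded from the denominator — the query-anchored convention of
  standard alignment-filtering tools. Pruning keeps rows with QID at or
  above the threshold; the query always survives.
- Thresholds run 1–50% in 1% steps; thresholds yielding identical row sets
  are collapsed (re-running identical alignments would bias the averaged
  z-scores by double counting).
- Gap preparation removes rows with >25% gaps (query exempt) and then
  columns with >75% gaps, in that order; the order is observable and
  contract-tested.
- A3M lowercase insert states are deletions relative to the query
  coordinate system; `.` and `-` both read as gaps.
- An alignment is deep enough for coupling inference when its depth is at
  least `5 × L`; shallower inputs are refused with a diagnostic.

## The stand-in coupling scorer

External Potts-model and language-model engines are consumed as score files
(pair lists or L×L matrices). The built-in scorer provides the same
interface without external tools: mutual information over the 21-state
alphabet (20 amino acids + gap) with an additive pseudocount of 1
distributed over the 441 joint cells, followed by average-product
correction `S(a,b) = MI(a,b) − m_a m_b / m`. Sequences are unweighted and
the gap is an ordinary state, keeping the score a deterministic function of
the alignment. Pairs closer than 6 residues in query coordinates are not
reported (near-diagonal couplings are dominated by chain connectivity;
configurable).

MI is an order-of-magnitude weaker instrument than a regularized Potts fit:
it detects the planted couplings of the synthetic benchmark reliably, but
its extreme-value noise floor fills most of the per-run retention quota
with spatially uniform false pairs. This matters for what the benchmarks
can show (below).

## Density filtering and the eps rule

Retained pairs are clustered in the (i, j) plane (half-plane `i < j`,
Euclidean distance, `min_samples = 3`). The implementation follows the
textbook DBSCAN definition with one determinism refinement: border points
join the cluster of their lowest-index core neighbor. Note that a DBSCAN
cluster can, in adversarial geometries, end up with fewer members than
`min_samples` when an earlier cluster claims its border points; the
implementation does not patch this over, and the randomized equivalence
tests compare against a pure brute-force reference.

The radius is chosen from an ROC table over an integer grid 1–15 (contact
coordinates are integral): for each eps, TP counts filtered pairs within a
±2-residue Chebyshev box of reference contacts, FP the rest. The selected
eps is the largest whose incoming marginal slope ΔTP/ΔFP exceeds 1 while
the next step's slope falls below 1; a step with ΔFP ≤ 0 has slope +∞ only
if it gains true positives, else 0 (a flat step is not an elbow).
Filtering may never be so stringent that it returns fewer contacts than the
deep-alignment baseline; this floor is enforced on both the total and the
correct (±2-overlap) contact counts, since protecting the total alone would
allow an eps that keeps accidental noise triples while discarding every
correct contact. If no grid value qualifies, the smallest eps meeting the
baseline floors is used; if none does, the largest grid value with a
warning.

The superfamily-only baseline used in all comparisons is the `3L/2`-pair
superposition of deep-alignment runs, density-filtered with its own
ROC-chosen radius.

## Structures and categorization

Structures are parsed with gemmi (PDB/mmCIF), hydrogens and waters
excluded, highest-occupancy altloc kept. Chains map to the query by global
alignment (match +1, mismatch 0, gap open −5, extend −1); chains under 15%
identity are refused rather than force-aligned. Contacts are minimum
heavy-atom distances: ≤8 Å intrachain (all separations ≥1 by default),
≤10 Å interchain, all in query coordinates.

The dual-fold map intersects two conformations' intrachain contacts
*exactly*; the ±2 tolerance applies only when predictions are compared to
experimental contacts. The dominant fold is the one whose unique contacts
(interchain included) overlap more of the deep-alignment predictions; ties
go to the first structure with a warning. Predictions are categorized with
precedence common > dominant > alternative > unobserved, so a pair
consistent with both folds never inflates a unique count. Interchain
contacts count toward their fold's unique set (a homodimer interface is
fold-specific evidence).

## Statistics

- **Enrichment p-value.** The one-tailed hypergeometric sum is evaluated
  exactly as printed — noise space `L² − N_exp` with `L` the maximum
  experimental sequence length, even though unordered pairs would halve it;
  the `*_total` denominators default to `N_exp`/`N_noise` with an override
  hook. Terms are computed in log space via log-gamma and summed with the
  usual max-shift; impossible binomial arguments contribute zero. Agreement
  with exact rational arithmetic is tested to 1e−9 relative error.
- **Epps–Singleton** wraps `scipy.stats.epps_singleton_2samp` (evaluation
  points 0.4/0.8 scaled by the pooled semi-interquartile range, small-sample
  correction) with an explicit degenerate-IQR guard; null calibration at
  α = 0.05 is verified by simulation.
- **Depth bins** are 0.05-wide with lower-edge labels, `floor(20·f)/20`
  capped at 0.95 (a fraction of exactly 1.0 lands in the 0.95 bin). Note
  one of the three worked bin examples circulating for this procedure
  (15,100/20,000 → 0.70) is inconsistent with any uniform flooring; the two
  self-consistent examples define the rule implemented here.
- **Enhancement profiles** accumulate each category's correct contacts from
  deep to shallow (bin b pools all alignments with depth fraction ≥ b, so
  bin 0.0 contains everything), then z-score the 20 per-bin counts within a
  family; a flat profile gives all-zero z-scores, and a profile needs at
  least two populated bins to be meaningful.

## Blind classification

DSSP 8-state strings collapse to 3 states (H,G,I→H; E,B→E; rest→C).
Divergence marks every position covered by *some* window of length ≥15
whose α↔β-difference density is ≥50%, reporting maximal merged spans — the
sustained-region rule is stated without a maximality convention, so
windows, not runs, define coverage. Corroboration counts filtered clusters
(≥3 members) touching a predicted structure's unique contacts within ±2.
"Substantial alternative signal" (Category 2) is operationalized
conservatively as a cluster of ≥5 pairs, mean sequence separation ≥6, with
no member within ±2 of either predicted structure's contacts; multimeric
interfaces can mimic this, so Category 2 calls carry an explicit flag.
When predictions diverge but only one structure is corroborated, the call
is Category 1 with a low-confidence flag — a documented extension for
partially supported switches. Divergence with no corroboration at all is a
single-fold call: predictor disagreement alone is not evidence of fold
switching.

## Synthetic benchmarks: what they show and what they don't

`generate_family` plants couplings as two-state column pairs drawn from a
fixed 2×2 symbol table in **every** row; only rows in the active stratum
(all rows for dominant pairs, the high-identity clade for alternative
pairs) draw the two symbols jointly, the rest draw them independently.
Marginal column frequencies are therefore identical inside and outside the
clade, and the superfamily-visible alternative signal is only the clade's
joint-frequency excess — the masking phenomenon itself, not a caricature of
it. Defaults: L = 100, 2,000 sequences, 15% clade, 8 dominant + 8
alternative pairs laid out as diagonal 4-contact stripes (real contact maps
are locally dense, and density filtering is only meaningful on spatially
clustered signal), coupling strength 0.9, background/clade identity
0.35/0.75 (typical superfamily vs subfamily levels), no indels. Identity is
controlled in expectation, not exactly.

With these defaults the pipeline recovers all planted alternative pairs
across seeds while the superfamily-only analysis recovers essentially none
— the desk-scale analogue of subfamily-driven enhancement. Two honest
limitations:

- The MI stand-in's retained cloud is ~90% uniform noise at this problem
  size, far noisier than production inference engines. DBSCAN therefore
  percolates at any radius ≥2 and removes only the sparsest points; the
  benchmarks accordingly test *preferential* noise removal (false pairs
  removed at a higher pooled rate than true pairs), not noise elimination.
- For the same reason, blind-classification properties (specificity on
  single-fold families, Category 1 sensitivity) are validated on
  `generate_blind_scenario` inputs — contact clouds with clusters on the
  predicted structures' contacts plus sparse scatter, matching the
  post-filtering composition real engines produce — rather than on the
  stand-in chain, whose dense noise would swamp any classifier. The full
  chain is still integration-tested end to end on dual-fold families.

Passing these benchmarks shows the machinery is correct and the enhancement
logic sound under controlled conditions; it does not by itself demonstrate
performance on real protein families, which depends on the external
inference engines and alignment quality.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs, and every CLI output directory carries
  a `manifest.json` with the full configuration.
- Z-scoring a zero-variance run yields all zeros with a warning rather than
  an error; empty categorization inputs and zero-baseline amplifications
  raise instead of returning NaN.
- Problem sizes in the test suite (families of 2,000×100, 10–20 seeds per
  property, 100 random instances for the clustering oracle) were chosen to
  give stable statistics at interactive runtimes.
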