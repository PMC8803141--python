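# Methods

This note records the models behind `tnfit`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices that matter when reading results.

## The measurement being modeled

A saturating mini-Tn5 library in a bacterial chromosome is a population of
mutants, each carrying one transposon insertion. Sequencing the
transposon–genome junctions gives, per sample, a map from (position,
strand) to read count: the insertion profile. Exposing the library to a
stress and re-sequencing changes per-gene read counts in proportion to the
fitness of that gene's insertion mutants under the stress. Two summary
statistics carry the analysis: the **insertion index** (unique insertion
sites in a gene divided by gene length), which reflects whether mutants in
the gene can exist at all, and the **log2 fold change** of read counts
between treated and control samples, which reflects conditional fitness.

## Synthetic-data generator

The generator's defaults are the study conditions the rest of the package
is tested under:

| parameter | default | rationale |
|---|---|---|
| insertion density | 1/10.3 per bp | density of the emulated dense mini-Tn5 library (~4.5×10⁵ sites on a 4.6 Mb chromosome) |
| mean reads per site | 10 | ≈ 4.4×10⁶ junction reads over ≈ 4.5×10⁵ sites |
| per-site NB dispersion α | 0.3 | variance μ+αμ²: realistic overdispersion for PCR-amplified junction libraries |
| mean gene length | 900 bp | typical bacterial gene; lengths gamma(shape 4), min 150 bp |
| demo genome | 50 kb, 40 genes | completes the full read-level pipeline in seconds |
| calibration genome | 4.2 Mb, 4,000 genes | chromosome-scale gene count for the statistical experiments |
| effect classes | loss log2 −3, gain +2 | order of magnitude of the strongest published conditional-fitness effects |
| treatment durations | scale 1.0 (early), 1.6 (late) | two durations modeled as scalings of one effect map, each compared to the same control pool |

Choices that define the model rather than tune it:

- **Genomes are linear**, coordinates 1-based inclusive; no origin-spanning
  genes or wraparound reads. Real chromosomes are circular; the
  simplification costs one gene's worth of realism and removes a class of
  edge cases from every downstream stage.
- **Site identity is (position, strand).** A mini-Tn5 inserts in either
  orientation and the junction read records which; a strand-collapse flag
  exists everywhere for the position-only convention.
- **Essential genes are fully insertion-free.** Insertion sites are drawn
  per-base Bernoulli outside essential gene bodies, so the unique-site
  count is Binomial(accessible bp, density). Tolerated 3′-end insertions in
  essential genes are not simulated; the analysis side offers a symmetric
  end-trim fraction instead.
- **Per-site read counts are zero-truncated NB.** A site with zero reads is
  unobservable, so counts are conditioned positive; otherwise the realized
  site count would fall ~1% below the Binomial expectation.
- **Treatment is multinomial resampling** of the control's total reads with
  per-site weights count × 2^(gene effect). Total reads are conserved
  exactly; a −∞ effect (hard kill) gives a gene zero treated reads.
- **Replicates share one master library.** Biological replicates of a real
  experiment are aliquots of the same physical mutant pool, which is why
  their per-gene insertion indices correlate at r² ≈ 0.97–0.98. Two
  *independently drawn* libraries would share no site-level structure and
  could not reproduce that agreement, so replicate samples are generated
  as independent read-level resamplings (neutral `apply_selection`) of one
  simulated master library. Simulated replicates agree slightly more
  tightly (r² ≈ 0.99) than real ones because depth variation, PCR
  jackpotting and plating bottlenecks are not modeled.
- **Reads** are barcode + transposon tag (default: the 19 bp mosaic-end
  sequence of EZ-Tn5) + genomic junction, truncated at replicon ends,
  constant Q30 qualities, i.i.d. substitution errors. No PCR bias,
  fragment-length model, quality decay, indels, or paired ends. The
  simulator keeps insertions `edge_margin` bp away from replicon ends when
  reads will be emitted, so that junctions are never truncated below the
  short-read filter — without this, terminal sites are legitimately lost
  in processing and the error-free round trip would not be exact.

Consequently, passing tests demonstrate correctness of the statistics and
bookkeeping under an idealized sequencing model; they do not demonstrate
robustness to adapter contamination, chimeric reads, uneven coverage or
mapping bias in repetitive genomes.

## Read processing

Barcodes must be prefix-free and match exactly (a barcode error costs the
read, conservatively). The tag match tolerates `max_mismatch`
substitutions (default 2). Junctions shorter than 20 bp after trimming are
dropped: 20 bp is the shortest length that places essentially uniquely in
a ~4.6 Mb genome. Mapping splits the junction into `max_mismatch + 1`
seeds (pigeonhole: at least one is error-free if the read is mappable),
looks seeds up in an exact k-mer index of both strands (k = 13 default),
and verifies candidates over the full junction allowing ≤ `max_mismatch`
substitutions, no gaps. Substitution tolerance in the verified region is
required for any realistic error rate — at 1% per-base error an
exact-match policy would discard most long junctions. Ties on the best
mismatch count are ambiguous and discarded. The reported position is the
first genomic base of the junction on the matched strand. A SAM ingestion
path (RNAME/POS/FLAG) exists for substituting an external mapper.

## Essentiality model

Indices are bimodal: essential genes at (exactly) zero, permissive genes
near the genome density (~0.097 sites/bp). The two-gamma EM operates on
`index + floor` with floor = 1/(2·longest gene), so a single insertion in
the longest gene still clears the floor; the left component fits the
resulting spike (its shape is capped at 10⁶, where it approximates a point
mass). Initialization is deterministic 2-means on log indices;
convergence is a log-likelihood improvement < 1e-8 for 3 consecutive
iterations. Calls use the log2 likelihood ratio with thresholds ±2 (an
odds ratio of 4 either way) and an ambiguous band between. Degenerate fits
— mixing weight collapsing below 10⁻³, or component means separated by
less than 10× — raise an error instructing a fixed-threshold fallback
(the pipeline then calls essential below insertion index 0.01, which at
default density corresponds to ~10× fewer insertions than expected).
These thresholds are design constants of this implementation; the model
family (gamma mixture on insertion indices) is the standard approach for
dense-library essentiality calling.

## Fitness statistics

Size factors default to library totals; a trimmed-mean-of-log-ratios
adjustment is available. The common dispersion φ is pooled method of
moments on depth-equalized within-condition replicates,
φ = max(0, Σ(v_g − m_g)/Σ m_g²), floored at zero. At gene level, counts
summed over ~90 sites are far less dispersed than per-site counts, so φ
near zero on simulated data is expected, not a bug.

The exact test equalizes replicate counts to the geometric-mean library
size (scaling and rounding — a deliberate simplification of quantile
adjustment), pools per condition, and enumerates every split k of the
pooled total T. Under the null both condition sums are NB with
per-replicate mean T/(n_c+n_t) and sizes n_c/φ, n_t/φ; the two-sided
p-value sums conditional probabilities of splits no more probable than the
observed one (tie tolerance 1+1e-9 on the probability comparison). At
φ = 0 the conditional law is exactly Binomial(T, n_c/(n_c+n_t)) and the
test reduces to the exact binomial test — both limits are verified against
independent enumeration oracles in the test suite.

Log2 fold changes use prior count 0.5 on both means, so a gene with zero
treated reads gets a finite, depth-dependent estimate. Under multinomial
resampling the fold-change estimates carry a small common compositional
offset (−log2 of the weight normalizer, ≈ 0.003 at the calibration scale);
it is ignored.

Bonferroni multiplies by the number of tested genes — non-essential genes
with at least one read in any sample; all-zero genes are reported with
p = 1 and not counted. The gate is strict on both axes (|log2FC| > 1 and
adjusted p < 0.005): a gene at log2FC −0.961 fails on magnitude however
small its p, and adjusted p = 0.0041 passes while 0.005 does not. The
enrichment threshold is deliberately *inclusive* (p ≤ 0.005) — the two
cutoffs are independent constants. Two treatment durations are compared
separately against the same control pool and their significant sets split
into shared / early-only / late-only.

## Enrichment and competition assays

Enrichment is the plain one-sided hypergeometric upper tail against a
user-supplied gene→term map; the background defaults to all annotated
genes and is configurable (all non-essential genes is the main
alternative). This is a transparent replacement for web-service annotation
tools, whose EASE-modified statistic is slightly more conservative; no
GO-DAG propagation and no multiplicity correction is applied.

The selection rate r = ln(Rt/R0) − ln(Vt/V0) is undefined when a
population is eradicated (Rt or Vt = 0); the default policy flags it
rather than imputing, because "zero surviving colonies" is a qualitatively
different outcome from a small count. A 0.5-pseudocount policy exists for
plotting. Zero baselines (R0 or V0 = 0) are a data error.

## Determinism and problem sizes

Every stage takes an integer seed; the pipeline derives per-sample seeds
from the master seed arithmetically, and two runs of the same config are
byte-identical. The calibration experiments (`tnfit.experiments`) use a
4.2 Mb / 4,000-gene genome — chromosome scale — with 10 repetitions for
the null experiment (40,000 gene tests), and the demo pipeline uses the
50 kb / 40-gene configuration; these sizes keep a full run to minutes on
one CPU while leaving the statistical conclusions stable across seeds.

## Known limitations

- No polar (promoter-out) effects on downstream operon genes; each gene's
  effect is independent.
- No tagwise or trended dispersion, no GLM framework, no FDR control other
  than Bonferroni.
- The essentiality EM assumes a genuinely bimodal index distribution;
  sparse libraries (density ≪ 1/100 bp) will trip the degeneracy guard.
- Circular replicons, multi-replicon genomes and paired-end reads are out
  of scope.
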