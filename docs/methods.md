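# Methods

## Coordinates and read parsing

All internal coordinates are 0-based half-open (BED convention).  SAM
input (1-based) is converted once at the parsing boundary: a record at
SAM POS p with an M-length CIGAR of L spans `[p-1, p-1+L)`.  Pairs are
accepted when both mates are mapped on the same chromosome in FR
orientation (plus-strand mate 5′ of the minus mate's 3′ end); pairs with
an unmapped mate, cross-chromosome pairs and orphan records are tallied
so that record counts partition exactly:
`total = 2·yielded + unmapped + improper + orphan + 2·low-quality`.

MAPQ filtering keeps pairs with `min(mapq_1, mapq_2) ≥ 10` (inclusive;
configurable).  Duplicates are defined on both mates' full coordinate
tuples, matching paired-end redundancy-removal semantics, and the
duplication rate is `1 − unique/total`.

## Tn5 transforms

The plus-strand insertion centre is `start_plus + 4`; the minus-strand
centre is `end_minus − 5`, i.e. 4 bp interior to the rightmost aligned
base — under the half-open convention this is symmetric with the plus
side and reproduces the standard +4/−5 ATAC correction with one stated
rule.  PE-asSE fragments are `[centre − 75, centre + 75)`, clipped at
chromosome bounds but kept with weight 1 so E_total is exactly twice the
pair count.  PE-noShift fragments span `[min(centre), max(centre) + 1)`;
coincident centres give a length-1 fragment rather than being dropped,
conserving the pair count.  Mitochondrial fragments are excluded from
useful ends by default (chrM is contamination, reported in the alignment
QC); whether E_total should include chrM is not fixed by convention, so
the choice is explicit, configurable, and recorded in the report notes.

## QC statistics

**Assignment rules.** Two rules are used deliberately: peak membership
for RUPr/ProEn/SubEn uses the ≥ 50%-overlap rule (stated for peaks);
region and per-peak *counting* (background RPKM, signal ranking,
count matrices) uses point containment of the insertion centre
(pseudo-SE) or fragment midpoint (noShift), which makes counts additive
and assigns each event to at most one merged peak.

**Background.** 50,000 regions of 500 bp are drawn uniformly over all
eligible start positions outside the merged peaks and off chrM (regions
may overlap each other); a region is high-background when its RPKM is
*strictly* greater than 0.377 ("over the threshold").  The 0.377
constant is treated as an opaque published default.  Note the threshold
is depth-relative: at desk-scale depths (10⁴–10⁵ ends) it corresponds to
≥ 1 read per region and BG saturates near 1; at the 10⁷-end depths the
defaults were calibrated for it corresponds to ≥ 2 reads.  Tests
therefore check BG against its Poisson-tail expectation rather than
against a nominal "good" value.

**ProEn.** Promoter peaks are the merged peaks with ≥ 1 bp overlap with
any promoter interval (±1 kb around supplied TSSs).  The genome length
in the denominator matches the EndSet's chrM policy (chrM bp subtracted
when mito ends are excluded) so that a uniform library has ProEn = 1.

**SubEn.** The printed form of the statistic is typographically
ambiguous; the canonical form used here is, with sampled in-peak ends
E_in, sampled total E_s, peak bp L_p, genome bp L_g and p = 10⁷ uniform
pseudo-ends:

    SubEn = [(E_in + p·L_p/L_g) / L_p] ÷ [((E_s − E_in) + p·(1 − L_p/L_g)) / (L_g − L_p)]

This satisfies the stated properties: it measures genome-wide
enrichment, equals the raw density ratio as p → 0, shrinks to 1 as
p → ∞, and cannot fail at low depth.  The report flags the metric as
`canonical-form`.  Libraries smaller than the 10⁷ sampling depth use all
ends and record the shortfall.

**Saturation.** Subsamples are nested (the 10% sample is contained in
the 20% sample, etc.) so recovery is monotone up to caller noise, and
recovery at full depth is 1 by construction.  Recovery compares
intersected bp against the full-depth peak set.

**Signal ranking.** Per-peak signal is assigned-end count per peak kb —
caller-independent by design.  Peaks are ranked descending and split
into 10 equal bins (remainder to the top bins); the quantile count is a
decile by default because no convention fixes it.

**Validation and grading.** A peak is validated by ≥ 1 bp overlap with
the reference set; unvalidated peaks / n_peaks is FDR-like, missed
reference elements / n_reference FNR-like.  Grading is
good ≥ mean, acceptable ≥ mean − SD for higher-better metrics, mirrored
for lower-better; boundaries are closed exactly as stated.  No reference
table ships with real cohort numbers — the table is a user input.

## Bundled peak caller

A deterministic Poisson-tile caller stands in for a model-based caller:
non-overlapping 150-bp tiles are scored by insertion-centre count
against the genome-wide rate λ = E_total·window/L_genome, upper-tail
p-values are Benjamini–Hochberg corrected across all tiles, and adjacent
tiles at q ≤ 0.01 merge into peaks (score = −log10 of the best q, summit
at the densest tile).  Non-overlapping tiles were chosen over sliding
windows for determinism and speed; the caller is a test harness and a
pluggable default, not a MACS2 clone, and any caller (or a static peak
BED) can be supplied wherever a `peak_caller` is accepted.

## Differential accessibility

Counts per merged peak use point containment, so PE-asSE registers two
events per fully contained pair and noShift one.  Counts are normalized
to counts-per-10-million (matching the track normalization); log2FC is
computed with a pseudo-count of 1 on the normalized group means (group2
over group1, groups ordered alphabetically).  The bundled significance
test is the exact conditional binomial test of equal Poisson rates on
summed raw counts with library-size exposures — valid for the
synthetic Poisson fixtures, but *not* a negative-binomial model: it
ignores biological over-dispersion and is documented as a stand-in.
Externally computed p-values (e.g. from DESeq2) can be injected per
peak.  DAR thresholds are strict as printed: padj < 0.01 and
|log2FC| > 1.  Nearest-TSS classes are proximal ≤ 2 kb (boundary
inclusive) and distal (2 kb, 20 kb]; annotation categories use midpoint
containment with precedence promoter > exon > intron > intergenic.

## Synthetic libraries

The generator plants non-overlapping peaks (default 60 peaks,
~500 ± 100 bp) on a 1.8 Mb + 20 kb chrM genome and draws 20,000 pairs:
with probability `p_peak` = 0.30 both insertion centres fall inside one
uniformly chosen peak, otherwise the pair is uniform background; insert
sizes come from a 0.45/0.40/0.15 mixture at 70/200/400 bp
(sub-nucleosomal / mono / di-nucleosomal — conventional values, chosen
to make the insert-size QC meaningful); 10% duplicates are exact
coordinate copies; 5% of pairs are mitochondrial; 5% carry MAPQ < 10.
These defaults describe a decent-quality library at a scale where the
full pipeline runs in seconds.  Closed-form expectations accompany the
generator: RUPr ≈ p + (1−p)·Σ(wᵢ+1)/L (the qualifying-centre measure of
a width-w peak under the 50% rule is w+1 positions), BG from the Poisson
tail at the background density, ProEn from the density ratio.

What the generator does not model: sequence content, GC bias, Tn5
sequence preference, chromatin-state autocorrelation, or dispersed
(non-exact) duplicates.  Passing tests therefore demonstrate that the
statistics and transforms are computed correctly and are calibrated
under their own sampling models — not that any particular real library
will grade well.

## Numerical and design choices

* Interval arithmetic runs on sorted numpy arrays over merged sets;
  every operation is cross-checked in the tests against per-bp
  boolean-genome oracles, exactly.
* Seeded sampling canonicalizes end order first (sort by chromosome,
  centre, span), so SubEn and saturation are invariant to input order
  and bit-reproducible per seed.  All stage seeds derive from one
  top-level seed via named substreams.
* bedGraph is the canonical track format (4-decimal values); bigWig is
  a binary container and intentionally out of scope.
* Track values are reads-per-10-million; coverage conservation
  (Σ value·width = normalize·Σ fragment bp / E_total) is asserted in
  tests.
* Degenerate inputs fail loudly with typed errors: undefined metrics
  raise `MetricUndefinedError` (CLI exit 4), malformed files
  `ParseError` (CLI exit 3).

## Known limitations

* The bundled caller has no local background model; broad copy-number
  artefacts would inflate calls on real data.
* The default differential test underestimates biological variance
  between replicates; use injected NB p-values for real designs.
* BG and SubEn are depth-relative at small E_total (see above).
* No blacklist support; background sampling excludes only peaks and
  chrM.
* Promoters require a user TSS list; no expression filtering of
  "active" genes is attempted.
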