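# Methods

`bemut` implements the analysis stack used to ask whether chronic NSAID
use restrains somatic genomic evolution in Barrett's esophagus (BE):
per-patient somatic mutation catalogs from purified epithelial biopsies
are compared between matched NSAID users and non-users across five
axes — trinucleotide mutation spectra and load, VAF-based clonality,
mutational signatures, pathway-level functional burden and diversity,
and somatic chromosome alteration (SCA) classes. Because per-patient
exome calls from such cohorts are controlled-access, the package ships
a synthetic cohort generator with full ground truth; every downstream
method is validated by recovering what the generator injected.

## Mutation catalogs and annotation taxonomy

A catalog row is one somatic SNV or indel: position (1-based), ref/alt,
trinucleotide context on the reference strand, VAF, gene symbols within
1 kb, and one of 15 annotation categories. Five categories count as
likely functional: exon-non-synonymous, 3'utr-exon, 5'utr-exon,
coding-splicing, utr-splicing. The ten non-functional names
(exon-synonymous, intron-coding-gene, ... , other) are a stable
partition chosen by this package; only the functional five drive any
statistic, so the exact non-functional split is inert. Intervals
(genes, arms, segments) are 0-based half-open internally.

## Trinucleotide spectra

Each SNV is referred to the pyrimidine of the mutated Watson-Crick
pair: purine-reference mutations are reverse-complemented, giving 6
substitutions x 16 flanking contexts = 96 channels, ordered as in
conventional signature tables (C>A, C>G, C>T, T>A, T>C, T>G blocks;
flanks in A,C,G,T order). The involution property (both strand
representations map to one channel) is enumerated exhaustively in the
tests. Group comparison follows two routes: an exact two-sided sign
test on the 96 per-channel differences of group medians (ties dropped),
and a tie-corrected two-group Kruskal-Wallis on total load. Note the
sign test treats channels, not patients, as units; it is a descriptive
spectrum-wide test and is not expected to be patient-level calibrated
(see Calibration).

## Statistical procedures

All tests return a common result record. The exact sign test and
two-sided Fisher test are verified against integer-arithmetic
enumeration oracles; Benjamini-Hochberg against the definitional
step-up rule. The "mixed-effects" arm-density comparison is realized
as a patient-level permutation test: the statistic is the difference of
group means of per-patient mean arm density (mutations per Mb of arm),
and patient labels are permuted, which preserves the within-patient
correlation across arms exactly. The multivariable model is OLS of
log(count + 1) on NSAID use, smoking, and TP53 status; log1p matches
the transform used for signature loads and stabilizes the
negative-binomial variance.

## Mutational signatures

De novo extraction runs KL-divergence NMF (multiplicative updates, best
of several random restarts) on multinomial bootstrap perturbations of
each patient's spectrum, matches the per-resample signatures to
reference centroids by Hungarian assignment on cosine distance, and
scores each signature cluster by its mean silhouette (cosine metric).
The selected rank maximizes mean silhouette among ranks k >= 2 whose
least stable signature clears 0.8; rank 1 is the fallback when no
multi-signature solution is stable — k = 1 itself reproduces trivially
(every bootstrap solution sits near the data mean), so it cannot be
compared by silhouette. Exposures are refit on the unperturbed spectra
by NNLS.

Refitting against a reference set uses greedy forward selection with
per-step NNLS re-optimization on the L1-normalized spectrum, stopping
when the squared error improves by less than 1e-4, then discards
weights under 0.06 and refits (the deconstructSigs convention). Samples
with fewer than 50 SNVs receive zero assigned counts from all
signatures and a flag. Signature loads enter group comparisons as
log(count + 1) OLS, including the composite contrast "never-smoker
NSAID users vs all others".

The packaged 96x30 reference matrix is a deterministic synthetic
stand-in (see `bemut.refsigs`): S1-like (C>T at NpCpG), S17-like (T>G /
T>C at CTT-type contexts), and 28 sparse Dirichlet columns. It is a
drop-in slot for any 96xK column-stochastic TSV in the same layout.

## VAF clonality

In >98%-pure diploid epithelium, VAF ~ purity x clone prevalence / 2,
so counts of mutations with VAF strictly above a threshold measure the
burden carried by expanded clones. Mutations inside any copy-altered or
cnLOH segment are removed first (background territory counts as
diploid-balanced). The threshold scan (default grid 0.05-0.50, step
0.05) runs a Kruskal-Wallis per threshold on per-patient counts (raw)
and on per-patient proportions (controls for total load). Per-threshold
flags at p < 0.05 are exploratory by design and are reported
uncorrected; a BH-adjusted column accompanies them, and any claim about
the scan as a family ("no threshold differs") should be read from that
corrected column.

## Pathway burden and diversity

SNVs and indels within 1 kb of a gene are assigned to every pathway
containing that gene (double counting across overlapping pathways is
intentional and documented). Per pathway, functional and non-functional
counts are compared by Kruskal-Wallis with BH control at FDR 0.2;
per-gene tests require >= 5 carriers in either group and use FDR 0.1.
Percent reduction is 100 x (1 - user mean / non-user mean), computed
from unrounded means.

Pathway diversity per patient is a Shannon index on gene-count-
normalized burdens: m_i = count_i / genes_i over the chosen pathway
subset, p_i = m_i / sum m_j, SI = -sum p_i ln p_i with 0 ln 0 := 0. A
patient with no burden gets SI = 0 (maximally concentrated); SI is
scale-invariant and bounded by ln(#pathways). The exact normalization
beyond the gene-count division is this package's definition.

## Copy-number segmentation and SCA classes

The caller takes an exome probe track (per-target tumour/normal
log-ratio; BAF at heterozygous germline sites). Change-points come from
greedy binary segmentation on the joint standardized (log-ratio,
|BAF - 0.5|) signal — both channels scaled by a robust MAD-of-
differences noise estimate — accepting a split when the summed SSE gain
exceeds 6 ln n; probes without a het site inherit the nearest
informative BAF deviation so they cannot fake a change-point. Per
segment, total CN = round(2 x 2^(lr - baseline)) with the baseline at
the mode of the log-ratio density, and minor CN from the mean BAF
deviation; adjacent segments with identical calls merge.

Classes: HD (total 0), loss (0 < total < ploidy), cnLOH (total =
ploidy, minor 0), focal amplification (total >= ploidy + 4 and length
<= 3 Mb; both thresholds configurable), balanced gain (total > ploidy,
major = minor), allele-specific gain (other total > ploidy), else
diploid. Genome doubling is called when major CN >= 2 over > 50% of the
assessable autosomal genome; when the flag is set, classification is
re-run at ploidy 4. A perfectly balanced whole-genome doubling is not
identifiable from relative log-ratio plus BAF alone (the mode baseline
absorbs it); WGD inference therefore operates on segments with known
allele-specific CN, as when segments come from the generator or an
absolute-scaled caller.

Arm-level SCA load intersects segments with the packaged hg19 arm
table (autosomes, centromeres excluded): MB per (patient, arm, class)
plus arm-length-normalized segment counts; segments crossing a
centromere split into both arms.

## The synthetic cohort generator

The generator's defaults are the emulated study conditions:

| parameter | default | provenance / rationale |
|---|---|---|
| group sizes | 41 vs 41 | study design |
| SNVs/patient | NB(290.93, sd 209.69) users; NB(402.49, sd 362.68) non-users | printed summaries |
| indels/patient | NB(17.95, sd 12.25) vs NB(22.42, sd 13.77) | printed summaries |
| capture | 96 Mb | exome + UTR capture scale |
| purity, depth | 0.98, 80x | stated purification and coverage intent |
| signature mixture | S17 .315, S1 .205, S9 .078, S5 .071, S8 .055, background .276 | printed cohort-wide shares; remainder spread over three background columns |
| smoker effect | S17 weight x2, renormalized | smokers enriched for S17 |
| per-patient weight jitter | Dirichlet, precision 25 | real cohorts vary per patient; gives NMF distinct profiles |
| TP53 | rates 6/41 vs 11/41, assigned with load^2 weighting | mutant-TP53/load association, without moving group means |
| clones | users (1.0, .5), (.35, .3), (.15, .2); non-users (1.0, .5), (.6, .3), (.25, .2) | non-users carry more high-prevalence clones |
| pathway effect | 50% reduction of functional hits in 9 of 35 pathways, users only | headline effect |
| SCA rates | Poisson per class; non-user focal-amp rate 0.217 (= -ln(1 - 8/41)), user 0; WGD probability 4/41 vs 0 | printed prevalences |

Negative-binomial loads use the (mean, sd) parameterization via the
method of moments, falling back to Poisson with a warning when
sd^2 <= mean. VAF noise is binomial read sampling at the configured
depth, with at least one supporting read (callers do not emit
zero-read variants). The pathway effect reassigns suppressed functional
hits to pathway-free genes rather than deleting them, so group total
loads stay at their configured means. The gene model is 4000 synthetic
10-kb genes evenly spaced over the hg19 arms; the 35 synthetic pathways
put the nine affected ones at 140-250 genes — sized so each carries
roughly 3-6 functional hits per non-user, enough for a 41-vs-41 cohort
to resolve a 50% reduction at high per-pathway power — and draw the 26
null pathways from the complement gene pool so "null" means null in
recovery tests.

What the generator does not emulate: read-level errors and mapping
artifacts, germline contamination, transcription-strand asymmetries,
regional mutation-rate covariates (replication timing, chromatin),
sub-gene functional structure, or inter-pathway topology. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the declared generative model, not that
the biological conclusions transfer to any particular real cohort.

## Calibration and problem sizes

With all effects switched off (`null_truth`: equal loads, shared clone
structure and SCA rates, TP53 decoupled from load), the patient-level
group comparisons — load KW, high-VAF count KW, per-pathway KW,
diversity KW, permutation arm-density test, and the NSAID coefficient
of the multivariable model — reject at close to 5% at alpha = 0.05
(measured over 200 seeded cohorts in the test suite; a 600-cohort
diagnostic put each in 0.04-0.05). Two group comparisons are
intentionally not in that band: the channel-level sign test (channels
are not independent patients) and the Fisher focal-amplification test,
whose discrete null support at realistic sparse prevalences caps its
attainable level near 0.02 — exact conditional tests are conservative
there by construction.

Simulation sizes in the test suite are fixed design choices: 100
cohorts for effect-recovery power, 200 for null calibration, 20 seeds
for NMF rank recovery, 50 replicates for refit accuracy, 20 noisy
tracks for the segment caller. The default end-to-end pipeline run
(82 patients, ~28k mutations) completes in well under ten minutes on a
single CPU.

## Known limitations

* The annotation taxonomy's non-functional names are a stand-in
  partition; swapping in a different 10-way split changes nothing
  downstream.
* The packaged reference signatures are synthetic; results about
  specific biological signatures require supplying a real 96xK matrix.
* The segment caller assumes the modal copy state is diploid and does
  not detect balanced whole-genome doubling from relative data.
* The threshold scan's per-threshold flags are exploratory; only the
  BH-corrected column controls the family-wise error over the grid.
* Indels carry categories and VAFs but no 96-channel context and do not
  enter signature analyses.
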