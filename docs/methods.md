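# Methods

This note records the models, conventions, and numerical choices behind each
analysis, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Coordinates and event model

All internal coordinates are 0-based half-open; conversion to 1-based
happens only when reading or writing VCF/SAM. Every analyzed event —
somatic SNV, small indel anchor, or 8-oxoG lesion — is tied to a reference
position; guanine-anchored analyses additionally carry a strand: `+` when
the damaged/mutated G is on the top strand (reference base G), `-` when it
is on the bottom strand (reference base C).

## Consensus variant filtering

SNVs must be present in every SNV-capable caller's set (default three:
Strelka2-, VarScan2-, and SomaticSniper-style call sets), indels in both
indel-capable callers (Strelka2/VarScan2-style). Identity is
`(contig, position, ref, alt)` after left-normalization: shared trailing
bases are trimmed while rotating the allele window leftward through repeat
tracts, then shared leading bases are trimmed. Without this, equivalent
indel representations from different callers would spuriously miss the
intersection. Multi-allelic records are split before keying. `FILTER=PASS`
is not required by default (callers are assumed to have applied their
somatic filters upstream); a `pass_only` flag enables it. Cross-sample
exclusion removes any key present in more than one sample (configurable),
across all samples loaded in a run; a position-only matching mode is
available as a flag, exact-key matching is the default. Burden fold changes
are ratios of group medians; group comparisons use a two-sided
Mann-Whitney U.

Germline/LOH separation is assumed done upstream (e.g. VarScan
processSomatic); this module does not re-derive somatic status.

## Lesion extraction

A capture read reports one lesion. Filters, in order: flag must be exactly
0 or 16 (any other bit — unmapped, secondary, duplicate, supplementary —
rejects the read); CIGAR must be exactly `<read_length>M` (default 150);
the contig must be on the whitelist (default chr1–22, X, Y; configurable
for synthetic contigs). The candidate position is the read's 5' column:
`pos0 = (POS-1) + offset` for flag 0 (strand `+`), and
`pos0 = (POS-1) + read_length - 1 - offset` for flag 16 (strand `-`),
with `offset` defaulting to 0. The candidate is kept only if its
strand-specific reference base is G. Because the G filter passes ~25% of
positions under a wrong offset but ~100% under the right one, the retained
fraction makes the position convention self-validating on real data; the
signed `offset` flag exists to probe alternatives. Rejection counts are
kept per reason and satisfy input = retained + sum(rejections).

## Spectra

SBS96 channels are pyrimidine-centered: purine-reference substitutions are
reverse-complemented (base and flanks) before assignment. Channel order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G; within each, 5' then 3'
flank in ACGT order), matching COSMIC catalog files. Lesions are displayed
in the C>A block using their pyrimidine-collapsed context — a presentation
convention for side-by-side comparison with substitution spectra, not a
claim that lesions are substitutions.

Indels use the 83-channel COSMIC layout. Counting conventions, stated
explicitly because published tools differ in wording: the homopolymer
length of a 1-bp deletion includes the deleted base; the run length of a
1-bp insertion excludes the inserted base; the tandem-repeat copy number of
a longer deletion includes the deleted copy. Microhomology classes apply
only when no adjacent tandem copy exists, taking the longest overlap
between the deleted sequence's prefix/suffix and its flanks. A and G single
bases collapse to T and C by complementation.

Refitting uses non-negative least squares (exact KKT solution via
`scipy.optimize.nnls`) against a fixed catalog whose columns are normalized
to sum to 1, reporting exposures in mutation counts plus the residual norm.
De novo signature extraction (NMF) is out of scope. Exposure correlation
retains samples with at least 20 attributed mutations on both signatures
and reports Pearson r of log2 counts (raw counts via flag); fewer than
three retained samples yields an undefined r, flagged rather than computed.
Cosine similarity can be restricted to the 16 C>A channels (`channels="CtoA"`)
since published comparisons are sometimes made within that block only.

## Chromatin-state densities

Segmentations must partition (overlap is an error). Density is
`count / footprint_bp * 1e6` (events/Mb). Events outside the retained
segmentation are reported as `unassigned`, never dropped. Two
repetitive/CNV-associated states are excluded by default (configurable);
their footprints are reported. Densities here are footprint-normalized
only — no trinucleotide correction — matching how state-level densities
are conventionally displayed; G-content normalization is available in the
strand-asymmetry machinery where it matters. For group comparisons the
per-sample group density is total events over total footprint of the
group's states (footprint-weighted, so splitting a state's intervals
changes nothing); the reference group (default heterochromatin) is compared
to each other group by two-sided paired t-test across samples, with
Bonferroni multiplication by the number of comparisons, capped at 1.

## Positional profiling

Windows are ±500 bp (a 1000 bp window) around single-position anchors.
Contexts are keyed by the top-strand trinucleotide, all 64 kept distinct —
no pyrimidine collapse here, since the expectation model enumerates
AAA…TTT. The expected count at offset `j` is `E_j = sum_c f_c * n_c(j)`
with `f_c` the genome-wide event frequency per context; `L_j =
log2(O_j/E_j)` is flagged missing (NaN) when either count is zero, never
±inf, and missing offsets are excluded from fits rather than imputed.
Events are counted in every overlapping dyad window (dyad arrays overlap at
192 bp spacing with 1000 bp windows); TF profiles instead assign each event
to its nearest midpoint, ties to the leftmost. Both behaviors are
switchable.

Smoothing is Savitzky–Golay with a 201-point window (the odd realization of
a 200 bp window, required by symmetric polynomial smoothing) and polynomial
order 3, with polynomial extrapolation at the ends (`mode="interp"`);
interior NaNs are linearly interpolated before filtering.

Periodicity is estimated by a least-squares periodogram: for each period on
an explicit grid, regress `L_j` on `{1, cos, sin}` and take the fraction of
variance explained; the argmax is the period estimate. The rotational band
is 8–15 bp at ≤0.05 bp resolution restricted to |j| ≤ 73 (the 147 bp
nucleosome core); the translational band is 150–250 bp at ≤1 bp resolution
over the full window. The regression formulation handles missing offsets
without imputation (unevenly-sampled data). Significance is an F-test of
the best sinusoid against the constant model; because the band is scanned,
this p-value is optimistic and is used only to gate phase labeling, not as
a calibrated test. A constant profile yields zero power and a
non-significant flag. Sinusoid fits (`a + b*cos(2*pi*j/P + phi)`) are linear
for fixed P and grid-initialized then locally refined for free P. Phase
labels follow the fitted curve: offsets within a quarter period of a
maximum are "inward" (histone-proximal), of a minimum "outward"
(solvent-exposed); non-significant fits label everything "intermediate".

## Strand asymmetry

Conventions, stated because external tools keep them internal: in a
rightward-replicating domain the top strand is the lagging-strand template
(its complement is synthesized continuously), so a `+` G event there is a
lagging-template guanine; leftward domains flip. For a gene on strand `s`,
a guanine on `s` is on the non-transcribed (coding) strand; on the opposite
strand, transcribed. Same-strand gene overlaps are merged; opposite-strand
overlaps are ambiguous and events there are excluded and counted. Rates are
events per Mb of strand-specific guanine, computed per mutation class
(G>T, G>C, G>A; lesions as a single class); composition normalization is
applied uniformly to both replication and transcription analyses. The
log2 ratio numerator is the leading template (replication) or the
non-transcribed strand (transcription), configurable. With ≥2 samples the
test is a two-sided paired t-test on per-sample rates; with one sample, a
chi-square against expected counts proportional to strand G content (df=1).

## Synthetic data generator

The generator emulates the statistical structure these analyses assume, at
desk scale: two 2 Mb contigs of i.i.d. bases (default uniform composition)
rather than a human genome — enough to exercise every formula with
realistic counting statistics while keeping the full suite under a minute
per scenario. Annotation tracks: dyads uniformly spaced (default 192 bp,
the nucleosome repeat length); a chromatin-state partition of ~20 kb tiles;
alternating left/right replication domains of 50–150 kb; non-overlapping
stranded genes of ~10–40 kb covering roughly half the genome; 500 TF-site
midpoints per contig.

Events are sampled without replacement (weighted Gumbel top-k) from all
candidate guanine positions (both strands) under the factorized intensity

    lambda(p) = state_mult(p) * (w_c / N_c)
              * [1 + A_t cos(2*pi*d_t/P_t)]
              * [1 + A_r cos(2*pi*d_r/P_r + phi)]   (|d_r| <= 73 only)
              * replication_odds(p) * transcription_odds(p)

with `d_r` the offset to the nearest dyad and `d_t` the distance along the
dyad array. The context term `w_c / N_c` (weight over availability) makes
the marginal context distribution of events converge to the normalized
weights — the property the spectrum checks rely on; a raw multiplicative
weight would instead convolve the weights with genomic context abundance.
Rotational modulation applies only within the 147 bp core, matching the
structural footprint; elsewhere only translational modulation acts. Strand
biases are odds multipliers on leading-template and non-transcribed-strand
guanines, so the expected log2 rate ratio equals log2(odds) exactly.
Without-replacement sampling keeps variant keys unique, so a planted set is
a valid call set.

Caller simulation drops each truth event independently per caller with the
configured false-negative rate and adds caller-private spurious calls at
guanine positions disjoint from the truth, making three-caller consensus
recall analytically `(1-q)^3`. The SAM fixture writes one full-length
alignment per lesion (flag 0 with the lesion at the leftmost column, or
flag 16 with the lesion at the rightmost column) plus planted contaminants
(clipped CIGARs, unmapped/secondary/duplicate flags, a decoy contig) that a
conforming extractor must reject.

All randomness derives from one root seed through named substreams (CRC32
of the stream name mixed into the seed sequence), so adding a generator
never perturbs another's output and every artifact is byte-identical across
reruns.

What the generator does **not** emulate: sequencing error and base
qualities, alignment artifacts, diploid genotypes and germline variation,
mutation clustering/kataegis, replication-timing covariance with chromatin
state, and real genomic sequence composition (repeats, CpG depletion,
isochores). Passing recovery tests therefore demonstrates that the
analyses measure what they claim under their stated assumptions — not that
those assumptions hold in any particular real dataset.

## Problem sizes and calibration choices

Recovery scenarios use n = 50,000 planted events on the 4 Mb genome,
giving per-offset expected counts of a few hundred in dyad profiles —
enough that a 0.3–0.5 amplitude modulation dominates Poisson noise, chosen
to mirror the event counts of a heavily mutagenized genome set at desk
scale. The null-profile flatness check uses a denser dyad array (50 bp
spacing): per-offset expected counts of ~1,000 put the analytic Poisson
noise floor of mean |L_j| near 0.036, comfortably inside the 0.05 bound;
at the default 192 bp spacing the floor itself (~0.07) would swamp the
check regardless of correctness. Consensus recall uses n = 10,000 with 10%
dropout (binomial SE ≈ 0.004 against a ±0.02 band). The chi-square
type-I-error check uses 2,000 replicates of 10,000 events (SE ≈ 0.005
against a ±0.01 band).

## Known limitations

- The ID83 classifier handles simple insertions/deletions; complex
  substitution-indels raise an unclassifiable error and are counted, not
  silently binned.
- The periodogram F-test ignores the multiplicity of the scanned band (see
  above); treat `power` and the recovered period, not the p-value, as the
  primary readouts.
- Cross-sample filtering assumes call sets are already per-sample
  consensus sets; applying it before consensus would over-remove.
- `GeneSet` excludes opposite-strand overlap regions entirely; expression
  levels are not modeled (a transcribed gene list is assumed filtered
  upstream).
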