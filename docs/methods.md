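# Methods

`sortscreen` models and deconvolves a pooled yeast surface-display screen:
combinatorial promoter x signal-peptide (SP) libraries assembled on a
modular-cloning (MoClo/YTK-style) grammar, sorted by FACS into fluorescence
gates, and read out by long-read amplicon sequencing of each sorted pool.
This note records the models, the defaults and why they were chosen, and
what the synthetic benchmark does and does not demonstrate.

## Part grammar and assembly model

A construct occupies five slots in fixed order — promoter (slot 2), signal
peptide + epitope tag (3a), coding sequence (3b), C-terminal fusion module
(4a, here the cellulose-binding module CBM), and the anchor/terminator
cassette (4b). Each part carries 4-nt fusion overhangs at both ends;
assembly is valid only when each junction's overhangs agree, and the
assembled sequence is scarless: the shared 4 nt appear once, so an n-part
assembly has length `sum(part lengths) - 4(n-1)`. Display and secretion
differ only in the 4b cassette (with/without the anchor ORF).

Elastin-like polypeptides are built from the repeat formula: one unit is
(VPGVG)5-(VPGAG)2-(VPGGG)3 taken twice, i.e. 20 pentapeptides = 100
residues; `build_elp(n)` concatenates n units. DNA-level ELP fixtures use
one fixed codon per amino acid, which makes the sequence deterministic and
highly repetitive — deliberately so, since repeat cross-hits (ELP2 inside
ELP4) are exactly the hard case the annotation has to resolve.

The real screen's part sequences are not published; the fixture registry
(`sortscreen.fixtures`) is synthetic. It preserves the features the
analysis is sensitive to: 20 promoters in three strength classes (the
strong class standing in for the pYTK009-pYTK015 bin), 4 SPs (MF, STA1,
SUC2, AMY), ELP2/ELP4/BLA/Mel1 coding sequences, and part lengths that put
a full display amplicon at ~2.3-3.3 kb. Promoter bodies are 450-700 nt —
the lower bound is chosen so that the shortest full amplicon stays above
the 2 kb filter even after net deletion noise; with shorter promoters the
length filter would selectively delete short-promoter genotypes from the
counts, a bias the real constructs do not have.

## Sorting model

Each genotype g has a mean log10 fluorescence mu_g assigned from a
(promoter strength, SP) lookup plus a small seeded genotype-level jitter
(SD 0.05 log10 units) so genotypes within a class remain distinguishable.
Defaults span the instrument range printed for the experiment (10^2
background to 10^5 positive control): strong+MF 4.8 down to weak+AMY 2.4.
A cell fluoresces Normal(mu_g, sigma) on the log10 scale with shared
sigma = 0.3, and is binned by three thresholds t_low = 2.7, t_mid = 3.2,
t_high = 4.2: low below t_low, an intentionally discarded band between
t_low and t_mid (the screen's excluded band between the low and medium
gates), medium to t_high, high above. Intervals are left-closed, so a cell
exactly at a threshold falls in the higher bin. The thresholds are a
choice — the experiment shows its gates only graphically — placed inside
the printed fluorescence span so that all three gates are populated and
the excluded band is material (~15% of cells under the default model).

## Read simulation

Each sorted pool is sequenced as `fwd_barcode + amplicon + rev_barcode`,
with genotypes sampled proportionally to their sorted cell counts. The
manifest gives both barcodes as forward-strand sequences; reads are
reverse-complemented with probability 0.5. Errors are per-base
substitution/insertion/deletion with defaults 0.03/0.02/0.03 (~8% total,
typical of recent nanopore chemistry at this read length; the experiment
reports no error rate). Two template-level artefacts are available:
`truncation_prob` deletes the CDS part scarlessly (the "false-high"
template: a construct that displays without carrying its cargo), and
`chimera_prob` concatenates a second amplicon (to exercise the
double-marker discard rule). Both default to 0. Quality strings are
constant `I` because nothing downstream is quality-aware. Barcodes are
24 nt with minimum pairwise edit distance 8, generated once by seeded
rejection sampling — the separation that makes error-tolerant
demultiplexing testable. All three stages are deterministic given their
seeds; the pipeline expands one global seed into per-stage seeds via
`numpy.random.SeedSequence`.

## Deconvolution

**Demultiplexing.** A barcode matches if its best infix alignment within a
150-nt window at the appropriate read end has edit distance <= 4 (<= len/6
for 24-nt codes; at pairwise distance >= 8 this keeps crosstalk far below
1%). Both read orientations are scanned. A read is assigned iff exactly one
forward and one reverse barcode match; two forward (or reverse) matches
give `ambiguous`, a missing one `no_fwd`/`no_rev`. This is the
full-amplicon rule: only reads spanning both barcodes enter the analysis.

**Length filter.** "At least 2 kb" is interpreted as >= 2000 nt inclusive —
the only reading consistent with "at least". Reads failing it are demoted
to `too_short` but keep their pool labels so per-pool attrition is
reportable.

**Orientation.** The CBM sequence is the 3' marker: it is aligned to both
strands and the strand placing it nearer the 3' end is kept (ties resolve
to + for determinism). No marker hit at >= 80% identity gives `no_marker`;
two disjoint marker hits on the chosen strand flag a chimera. Marker
presence is required before genotype calling but not for pool-assignment
counts, which report demultiplexing alone.

**Annotation.** Coordinates are 0-based half-open internally and converted
to 1-based inclusive only at GFF3 emission. Each registry part is placed on
the oriented read in two stages. A semi-global (infix) edit-distance
alignment (edlib) places the full part; candidates whose best distance
exceeds `len * (1 - min_identity + 0.05)` are rejected — a part acceptable
after local trimming can exceed the naive `(1 - min_identity)` bound
slightly, hence the margin, while true hits at ~8% error sit far below it.
If the placed alignment's column identity already clears `min_identity`
(default 0.8) the hit is accepted outright, with coverage 1.0 by
construction and the affine score of that alignment (match +2, mismatch -3,
gap open -4, extend -2). Borderline candidates are rescored by local
affine-gap alignment (Biopython `PairwiseAligner`, same scoring) restricted
to the located window, which may trim to a cleaner sub-region — higher
identity at reduced coverage — and must then clear both `min_identity` and
`min_coverage` (default 0.8). This two-stage design is a performance
choice: scanning the whole registry with local alignment alone costs ~30 ms
per read, the two-stage path ~2-3 ms, with identical accept/reject
behaviour on the fixtures. One consequence: a fast-path hit's score is the
score of the edit-optimal alignment, a lower bound on (and in practice
within a few points of) the local-alignment optimum; exact-hit and
rescored-hit scores are optimal. Promoters are the one exception to the
coverage floor: a promoter hit flush with the 5' barcode junction (within
40 nt of the read start) is accepted down to coverage 0.5, because the PCR
primer can clip 5'-terminal parts; such hits are flagged `clipped_5p`.
Overlapping hits of the same slot keep the higher score, then the longer
alignment — this is what resolves ELP2 sub-hits inside ELP4 reads, and the
secretion cassette inside the display cassette.

**Calling.** Hits map to slots by their registry role, never by abundance
priors. A `full` call requires exactly one accepted hit in each of
promoter, sp, cds and 4a, in left-to-right order (4-nt junction overlaps
plus 20 nt of alignment fuzz are tolerated). Promoter + sp + 4a without a
cds is `truncated_no_cds` — the false-high class. Two accepted hits in one
slot, or an order violation, give `ambiguous`; fewer slots `partial`; none
`uncallable`. Only `full` calls enter abundance tables, consistent with
restricting the analysis to full amplicons.

## Quantification

Counts are tabulated as a promoter x SP matrix per (library, gate) pool in
fixed registry order; fractions divide by the pool's full-call count, which
is the denominator used throughout. A configurable floor (default 1000 full
reads per pool, mirroring the screen's stated analysis depth) triggers a
warning, not an error. Cross-gate enrichment is summarised per genotype as
`sum(w_g * f_g) / sum(f_g)` over gates with weights low 0, medium 1,
high 2, where f_g is the genotype's fraction in gate g — a depth-invariant
scalar in [0, 2] (2 = found only in the high gate). The weights are an
artifact convention enabling automated rank-recovery testing; the original
analysis ranks by inspection.

## Benchmark sizes and what passing shows

The shipped checks use: 9 pools x 500 noise-free reads for the end-to-end
identity check; ~2,000 noisy reads for call accuracy and per-cell abundance
(each cell within 3 binomial SDs of the simulated truth); 1,000 reads per
gate for rank recovery (Spearman >= 0.8 between true mu and the recovered
score; observed ~0.99); 1,000 random instances for the brute-force oracle
equivalence of barcode matching; 10^4-10^5 cells for the sorting-model
CDF convergence checks. These sizes keep a full run in tens of seconds on
one CPU while leaving binomial error bars much tighter than the margins
being tested.

The generator emulates barcode structure, amplicon composition, indel
noise, strand randomness, truncation and chimerism. It does not emulate
basecaller-specific error profiles (homopolymer compression, quality-error
correlation), PCR amplification bias, cell growth between sorting and
sequencing, or real YTK sequence content — so passing tests demonstrate
the correctness and error-tolerance of the deconvolution logic under a
realistic noise budget, not performance on any particular real flow cell.
Known limitations, beyond those: the fluorescence model is a single-sigma
log-normal per genotype (no bimodal non-displaying subpopulation beyond the
background mean, no instrument saturation), uniform library composition is
assumed by default, and enrichment is reported without significance
testing.
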