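# Methods

## The measurement model

Bisulfite converts pseudouridine into a monoadduct that reverse
transcriptase traverses while skipping the base, so a Ψ site appears in an
alignment as reads whose CIGAR carries a deletion (D) at the reference
position. Everything in this package derives from a three-parameter
generative model of that readout. At a site with true stoichiometry
*x* ∈ [0, 1]:

- a fragment is modified with probability *x*;
- modified fragments drop out of the library with probability *A*
  (adduct-bearing templates amplify and ligate less efficiently);
- surviving modified reads delete the site with probability *R*, the
  motif-dependent conversion efficiency;
- unmodified reads delete it with background probability *B* (polymerase
  slippage plus residual chemistry at unmodified U).

The observed deletion rate among surviving fragments is

    y(x) = [x(1−A)R + (1−x)B] / [x(1−A) + (1−x)]
         = (B + (R − A·R − B)·x) / (1 − A·x),

a strictly increasing function of *x* whenever R > B and A < 1 (derivative
(R−B)(1−A)/(1−A·x)² > 0), with y(0) = B and y(1) = R. The simulator's
`oracle_expected_rate` evaluates the first form in exact rational
arithmetic; the calibration module's `predict_deletion` evaluates the
second in floating point; tests assert their identity to 1e-12, which
pins both implementations to the same mechanism by two independent routes.

Stoichiometry estimation inverts the curve,
x̂ = (y−B) / (R − A·R − B + A·y), clamped to [0, 1]. Clamping rather than
erroring is deliberate: binomial sampling routinely produces observed rates
slightly below B or above R, and those observations mean "0" and "1", not
"invalid".

## Calibration fitting

(A, B, R) are fitted per 5-mer motif from a spike-in dilution ladder
(default levels 0/20/40/60/80/100% Ψ; arbitrary grids with ≥3 distinct
fractions are accepted) by bounded least squares on the rates
(`scipy.optimize.least_squares`, trf, box bounds 0 ≤ A ≤ 0.99,
0 ≤ B, R ≤ 1). Initialization is deterministic — B₀ = rate at the smallest
fraction, R₀ = rate at the largest, A₀ = 0 — so identical input yields
identical parameters. The objective is unweighted by default; every ladder
level has the same nominal coverage in the assay, and equal weighting keeps
the fit's behavior transparent. Binomial-variance weighting is available
(`weights="binomial"`) but off by default. A flat series (all rates equal)
is rejected as unidentifiable rather than fitted.

Motifs without their own ladder resolve through a fallback. The shipped
default (A=0, B=0.005, R=0.6) is deliberately conservative: most 5-mer
contexts convert at well above 60% deletion at full stoichiometry, so an
understated R can only understate x̂, never inflate a site into the called
set. Motifs containing N (reference edges) always use the fallback. When
ladders were generated for a generic context (e.g. the NNUNN pool), the
fitted curve can be promoted to fallback via `--fallback-motif`. Whether
one should fit per exact 5-mer or pool related motifs is a design choice;
we fit per 5-mer and leave pooling to the caller's table construction.

## Pileup conventions

Coordinates are 0-based half-open internally; reports add a 1-based column.
A read contributes to coverage at every reference position it spans via
M/=/X or D — i.e. the deletion-rate denominator includes the deleted reads
themselves, so coverage = (spanning reads without deletion) + del_count
holds as an exact conservation law (property-tested against a naive
position-set replay oracle). Insertions and clips contribute nothing; N
skips advance without covering; unmapped/secondary/supplementary records
are skipped. Base quality and MAPQ carry no thresholds by default (a MAPQ
floor is configurable but defaults to 0).

"Internal" deletion: a D operation counts toward del_count only when at
least `min_flank` (default 2) aligned reference bases flank it on both
sides within the read. End-proximal deletions are overwhelmingly alignment
artifacts; requiring two anchored bases on each side removes them while
leaving genuine mid-read signatures untouched. Multi-base deletions count
every deleted position and are taken as left-aligned as emitted by the
aligner; homopolymer ambiguity is not re-normalized here but handled
downstream by the neighbor-U exclusion. References are assumed to be
sense-strand transcript sequences; genome-strand bookkeeping belongs to the
aligner upstream.

## Site calling

All published thresholds are implemented as strict inequalities exactly as
phrased ("above 5%", "below 1%", "above 20", "more than ten"); boundary
values fail. The coverage criterion applies to both libraries. The
expression floor is inclusive (RPKM ≥ 1.5), since 1.5 is described as the
lowest admissible level. Background rates for motifs absent from the
0%-probe table use a 0.01 floor so the 1.5-fold criterion never compares
against zero.

The neighbor-U exclusion needs a reference set of known sites. When one is
supplied, a candidate adjacent to a known site is dropped — unless the
candidate is itself in the known list, because adjacent genuine Ψ pairs do
occur (rRNA clusters). When no list is supplied the rule is applied
reflexively: among otherwise-passing sites, a site immediately adjacent to
a higher-rate passing site is dropped, exact ties keeping the 5′-most.
This targets the actual failure mode (a single deletion signature smeared
across a UU homopolymer) without requiring external annotation.

A passing site's tier is "confident" iff its treated deletion count
strictly exceeds 10, else "candidate".

## Downstream profiling

- **Writer assignment**: a site is hypo-regulated by an enzyme when its
  fraction falls by ≥50% (relative) on knockdown, hyper-regulated on a
  ≥50% relative rise, else independent. The 50% default is this package's
  choice — the qualitative description it operationalizes ("responded to
  knockdown") carries no published number — and it is exposed in the API
  and recorded in output metadata.
- **Ψ-strength**: per-gene sum of site fractions, partitioned at 1.0.
- **Metagene**: 1–2–1 segment layout with 25/50/25 bins over
  5′UTR/CDS/3′UTR, the standard convention; transcripts without UTR
  annotation are reported as "CDS-only" and excluded from densities.
- **Stop codons**: a Ψ within the final CDS codon renders as Ψ at its
  codon position (ΨGA/ΨAA/ΨAG for first-position sites); the 3′UTR is then
  scanned in frame for the next UAA/UAG/UGA and its offset in codons
  reported.
- **Tissue specificity**: "shared" = fraction > 0.5 in ≥1 tissue and
  > 0.10 in ≥4 tissues (the published definition); "tissue-specific" is
  defined here as its natural complement — > 0.5 in exactly one tissue and
  < 0.10 in every other assayable tissue. Absence (not assayable) is
  distinct from zero throughout.

## The simulator and what it does (not) show

`simulate_transcriptome` draws random transcripts (default length 120 nt,
configurable GC), plants one Ψ per transcript at a uridine inside the
window covered by every read, and generates reads of fixed length (default
100 nt) with uniformly random starts. Treated reads follow the generative
model exactly — per-fragment modification, dropout as fragment removal
before sequencing, deletion Bernoulli draws — and additionally apply the
background rate B at every other uridine, since bisulfite background is a
property of the chemistry, not of modified positions. Both libraries carry
uniform sequencing deletion errors (default 0.001/base, a typical
short-read indel error magnitude; configurable). Input libraries carry
errors only. Simulated deletions are 1 base at the site (an optional
2-base mode exists, off by default) and are never placed within the flank
gap of a read end, so the pileup's internal-deletion rule recovers every
simulated event and the generated SAM re-read through the pileup
reproduces the simulator's internal counts exactly (asserted in tests).
An optional per-site coverage-attenuation map models the RT-stop coverage
loss seen near dense Ψ clusters; it is off by default.

Default generative parameters are A=0.2, B=0.01, R=0.8 — a mid-range
dropout, a background at the input-filter boundary scale, and a conversion
efficiency typical of the majority of 5-mer contexts. Problem sizes used
by the shipped checks were chosen by power analysis before running them:
ladder recovery uses 5,000× per level over 50 seeds; stoichiometry RMSE
uses 1,000× over fractions 0.1–1.0; end-to-end recovery uses 100 sites at
500× (at that depth a site planted exactly at the 0.10 fraction floor is
estimated below the floor with non-trivial probability only from binomial
noise, and the strict <1% input filter is essentially never tripped by a
0.001/base error process); the input-background bound uses 50 sites at
10,000×.

What passing these simulations does **not** show: the generator emulates
the deletion signature, not real libraries. Reads are uniform-coverage,
error rates are position-independent, there are no PCR duplicates, no
quality-score structure, no mapping ambiguity, no splice junctions, and
per-motif conversion heterogeneity only enters if configured. Recovery
rates on simulated data are therefore an upper bound on real-data
behavior, and the calibration-accuracy results say nothing about how well
a ladder fitted on synthetic probes transfers to cellular RNA contexts.

## Numerical and degenerate-input choices

- Count tables reject del_count > coverage, duplicate (reference,
  position) rows and non-integer counts at construction.
- `deletion_rate` raises at zero coverage rather than returning 0/NaN.
- Fit parameters are kept strictly inside the open invariant bounds
  (A < 1, B < R) and a fit collapsing to B ≥ R raises as unidentifiable.
- All floats in output tables are formatted with %.6g, which is what makes
  rerun outputs byte-identical across platforms.
- Every stochastic entry point requires an explicit seed; all randomness
  flows through a single `numpy.random.Generator` per run, and the draw
  order is fixed, so identical (config, seed) gives byte-identical FASTA,
  SAM and truth files.

## Known limitations

- BAM input is not supported (text SAM only); convert upstream with
  samtools if needed.
- The caller holds count tables in memory; transcriptome-scale tables fit
  comfortably, but per-chromosome genome pileups should be split upstream.
- GTF models require exon/CDS (and optionally stop_codon) records with
  `transcript_id` attributes; CDS extent is taken as the min/max over
  records, which assumes no ultra-complex trans-splicing.
- The reflexive neighbor-U exclusion inspects immediate neighbors only;
  deletion smear across runs of ≥3 uridines longer than 2 nt is not
  re-resolved.
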