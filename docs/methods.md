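# Methods

This note documents the models and procedures `wormforge` implements, the
defaults it ships, the numerical choices behind them, what the synthetic
data does and does not emulate, and known limitations. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute at run time.

## Coordinates and gene models

All internal coordinates are 0-based half-open on the reference (+) strand;
conversion to/from the 1-based inclusive convention happens only at the
GFF3/BED boundary. This keeps every piece of cut/arm/amplicon arithmetic in
one convention. A `GeneModel` keeps its CDS intervals ordered 5′→3′ in gene
orientation and its spliced coding-strand sequence; when a gene has several
mRNAs the longest CDS is kept, with ties broken by the lexicographically
smallest transcript id (a deterministic rule; the choice among equal-length
isoforms is otherwise arbitrary). Gene models must start with ATG, have
length divisible by three and contain no internal stop; violations raise
errors naming the gene. N bases are allowed in the genome but rejected
inside any designed homology arm or amplicon.

## Protein identity and paralog grouping

Pairwise identity uses a global (Needleman–Wunsch, affine-gap) alignment
with match +1, mismatch 0, gap open −5, gap extend −1, computed with
Biopython's `PairwiseAligner`; identity is the number of identical aligned
positions divided by the length of the shorter sequence (the CD-HIT
convention). The scoring is fixed so identity values are exactly
reproducible; because co-optimal alignments can trade an identity for a gap
placement, the reported value is the first optimal alignment's count, and
the test suite checks it against an independent dynamic program's bounds
over all co-optimal alignments.

Clustering is greedy representative clustering: genes sorted by protein
length descending (ties by id), each joining the first cluster whose seed
exceeds the identity threshold *strictly* (>0.40 mirrors a ">40%" cutoff),
else seeding a new cluster. Greedy-by-representative is deterministic,
order-canonical, and matches how large-scale sequence clustering tools
behave; it deliberately does not re-evaluate membership against all cluster
members.

Group assignment then packs genes under the strain constraints: identity
clusters are split in order into chunks of at most `max_group_size`
(default 6 — two rounds of injections at three genes each); leftover
singletons join a same-subfamily group on the same chromosome within
`linkage_window_bp` (default 50 kb; "closely linked" is not a quantified
notion, so this is an exposed parameter, logged in the manifest); a
user-supplied pairing table can stand in for phylogenetic rescue
(`phylogeny_stub` — tree inference is out of scope); the rest are packed by
the numeric order of gene names within each subfamily; and genes flagged
`reserved` (well-characterized receptors kept as single mutants) always
become singleton groups. Subfamily homogeneity is enforced throughout —
mixed clusters are split before packing. Injection planning partitions each
group, in listed order, into consecutive rounds of at most 3.

## STOP-IN cassette design

Cut sites are SpCas9 NGG sites scanned on both strands within the CDS; the
blunt cut is modeled 3 nt 5′ of the PAM (no staggered cuts). Sites are
ranked by CDS offset — earliest truncation first — and sites in the 5′ half
of the CDS are flagged preferred.

The repair template is `left_arm (35 nt) + cassette + right_arm (35 nt)`,
with arms copied verbatim from the reference flanking a deleted interval of
`del_len` nt (default 7, configurable 4–30) centered on the cut and clamped
into the containing exon. The cassette is

```
TAAGTAAGTAA + <enzyme site> + TGATAA [+ A padding]
```

`TAAGTAAGTAA` reads as a stop codon in all three frames, so translation
terminates regardless of which frame the ribosome is in downstream of any
upstream indel; the trailing `TGATAA` adds further stops after the enzyme
site. Padding appends A's until (insert length − del_len) mod 3 = 1, so the
net length change is never a multiple of three and the edit is a frameshift
even if the stops were somehow read through. Padding never trims, which
preserves the triple-frame-stop property for 8-cutter sites. For
minus-strand genes the cassette is reverse-complemented before placement so
the stop codons read on the coding strand; all default enzyme sites are
palindromic, so site counting is strand-safe.

The enzyme is the first entry of a 10-enzyme 6/8-cutter table (EcoRI,
HindIII, BamHI, NheI, XhoI, SalI, NotI, PstI, KpnI, SpeI) whose site is
absent from a ±1 kb halo around the cut in the wild type — a superset of
any legal 400–1000 bp amplicon, checked because the actual amplicon is
designed afterwards — and occurs exactly once in the edited sequence. Site
uniqueness is amplicon-local, not genome-wide: the genotyping readout is a
digest of the PCR product, so only the amplicon matters.

Genotyping primers are exact reference substrings of 18–25 nt with GC
40–60% and no mononucleotide run over 4 (simple composition rules; melting
temperature models add little for a presence/absence digest assay and are
out of scope). Placements are searched so the wild-type amplicon is
400–1000 bp and the single enzyme site splits the edited amplicon into two
fragments, each ≥100 nt and differing by ≥50 nt, so both bands resolve on a
gel. The digest cut position is modeled at the midpoint of the recognition
site; real enzymes cut at defined offsets within the site, which shifts
band sizes by at most a few nt and affects no design constraint.

`validate_design` re-checks every invariant (arm lengths and reference
match, frameshift, triple-frame stops, site uniqueness and wild-type
absence, amplicon and fragment bounds, deletion placement) and reports a
per-check pass/fail record.

## Allele verification

Variant-call records (consumed from caller output or simulated; read
mapping and CNV calling themselves are not reimplemented) pass a confidence
filter: strictly more than 8 supporting reads and presence in at most 6
samples of the batch — the sharing cap reflects edits inherited from a
common parental strain, and both bounds are parameters. The observed locus
(edited region ±20 bp flanks) is globally aligned to the predicted edited
allele under the same scoring as the identity computation, and the mismatch
count is substituted columns plus gap columns — gaps count toward the
2-mismatch budget, stated explicitly because a "≤2 mismatches" rule is
otherwise ambiguous about indels. Classification: 0 mismatches →
`disrupted_exact`; 1–2 → `disrupted_mismatch`; >2 with structural flags →
`disrupted_larger_cnv`; >2 without flags → `needs_curation` (the output TSV
carries a `manual_override` column; the package never auto-resolves those);
no variant → `unedited`; filter failure → `low_confidence`.

## Screen statistics

The index formulas are implemented exactly as printed on the plate layouts:
quadrant CI = (N_odor − N_control)/(N_odor + N_control); distal CI =
(N_odor_circle − N_control_circle)/N_total_on_plate (animals outside both
circles still count in the denominator — forced by the formula); sector
score = Σ of values 3, 2, 1, −1, −2, −3 over visited sectors A–F; avoidance
= N_off_lawn/N_total with occupancy its complement; relative change =
(mutant − wild type)/wild type for both avoidance and mean survival days.
Undefined cases (empty plates, zero wild-type denominators) return NaN with
a warning rather than raising, so one bad plate never aborts a screen
summary.

Hit calling is deterministic and strict: the repellent rule flags CI
strictly above −0.5 (a strain that fails to avoid), and quantile rules flag
strict tail exceedances of relative change (default q = 0.05 — screens mark
hits graphically, so the quantile is a parameter, not a claim). Hypothesis
tests (Welch, ANOVA, log-rank) are routine and delegated to standard
statistics libraries by the user; the package's contribution is the index
computation and deterministic flagging.

Photobleach correction fits y = a·e^(−bt) by ordinary least squares on
log-transformed values over the pre- and post-stimulus windows only (first
30 s and last 20 s of each recording), never the response window; b is
constrained ≥0 and a degenerate fit returns the input with a warning flag.
The corrected trace is y divided by the fit, so a response-free recording
becomes constant 1. ΔF/F₀ uses F₀ = mean of the corrected trace over the
5 s before odor onset. Response-profile correlation across conditions is
Pearson by default (Spearman by flag), pairwise-complete with at least two
shared conditions per strain pair.

## Synthetic data: what it emulates and what it does not

Gene families are a random ancestor plus descendants diverged by
independent per-site substitution at rate 1 − target identity (the ancestor
is the family's first member, so it seeds the family's cluster); realized
identity to the ancestor concentrates at the target for long proteins.
Back-translation uses one fixed codon per amino acid — identity targets are
defined at the protein level, which is what clustering consumes — and every
emitted CDS is re-sampled until it carries an NGG protospacer in its 5′
half. The toy genome is one chromosome of single-exon plus-strand genes
separated by random spacers (multi-exon and minus-strand handling is
exercised by hand-built fixtures in the tests).

Editing outcomes plant known truth: the predicted allele verbatim (reads ~
10 + Poisson(20), comfortably above the >8 filter — only the relation to
the threshold matters); 1 or 2 substitutions in the insert-proximal window;
≥3 substitutions plus a random structural flag; no variant; or the exact
sequence with ≤8 reads. The default mode mix (74% exact, 3%+3% mismatch,
12% flagged structural, 4% unedited, 4% under-supported) follows the
verified-allele composition reported for a large knockout library, with
small mass added to the two failure modes so every classifier branch is
exercised.

Screens are binomial worm placement (quadrant CI has expectation 2p − 1),
Weibull survival times (shape 2) scaled to the configured mean with
per-genotype multipliers, and fluorescence traces
a·e^(−bt)·(1 + amp·boxcar) + Gaussian noise (defaults: 120-s recording,
0.25-s frames, onset 60 s, duration 10 s, bleach rate 0.02 s⁻¹, noise 1% of
baseline). Defaults mirror the assay scales of the study design: 150
animals per plate, 3 replicates, 30 animals per survival assay, wild-type
mean survival 5 days on a killing pathogen.

Passing tests on these data show the pipeline's arithmetic, rules and
round-trip guarantees are correct under the stated generative assumptions.
They do not show robustness to what real data add: sequencing error and
coverage variation, heterozygous and mosaic animals, repetitive loci where
arms or primers are non-unique genome-wide, intron structure interacting
with cassette placement, codon-usage and GC structure, or behavioral
covariates (age, density, plate effects).

## Problem sizes

The reference simulated study is 20 families × 3 members (60 genes of 250
aa), 50 clustering-recovery trials, 500 simulated records per editing
outcome mode, 1000 simulated chemotaxis plates, and 200 correlation-pairing
simulations — sizes at which the binomial and substitution-process
expectations quoted above are tight while the whole suite and the
acceptance script run in seconds.

## Known limitations

- Guide efficiency, off-target search and chromatin context are out of
  scope; cut-site choice is purely positional (earliest CDS truncation).
- Primer design is composition-based; no thermodynamic or cross-dimer
  checks.
- The greedy clusterer does not reproduce CD-HIT's k-mer prefilter
  heuristics, only its identity definition and threshold semantics.
- Verification assumes one allele per locus per strain record; diploid
  genotype likelihoods and mosaicism are not modeled (the in-silico digest
  does report a heterozygous-like three-band pattern for allele pairs).
- The exponential bleach model is single-component; recordings with
  two-phase bleaching will correct imperfectly.
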