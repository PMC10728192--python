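"""Sequencing-based verification of edited alleles.

Variant-call records at targeted loci (consumed from an upstream CNV/indel
caller, or simulated) are filtered by read support and sample sharing, the
observed edited sequence is globally aligned to the predicted ssODN product
(edited region plus 20 bp of flanking sequence), and each allele is
classified: exact repair, repair with at most two mismatches, a larger
structural event, a case needing manual curation, unedited, or low
confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .cassette_design import GenotypingAssay, SsODNDesign
from .genome_io import reverse_complement

__all__ = [
    "VariantCallRecord",
    "AlleleCall",
    "STRUCTURAL_FLAGS",
    "filter_call",
    "compare_to_ssodn",
    "classify_allele",
    "insilico_genotype",
]

STRUCTURAL_FLAGS = {"insertion", "deletion_large", "duplication", "inversion", "complex"}

# Same scoring as the identity alignments used for clustering, so the
# mismatch budget is defined on one alignment convention throughout.
_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-5,
    extend_gap_score=-1,
)


@dataclass
class VariantCallRecord:
    """One observed edited locus with its caller evidence."""

    strain_id: str
    gene_id: str
    observed_locus_seq: str  # edited region +- 20 bp flanks; "" if no variant
    supporting_reads: int
    n_samples_sharing: int
    structural_flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.supporting_reads < 0 or self.n_samples_sharing < 0:
            raise ValueError("read/sample counts must be non-negative")
        unknown = self.structural_flags - STRUCTURAL_FLAGS
        if unknown:
            raise ValueError(f"unknown structural flags: {sorted(unknown)}")


@dataclass
class AlleleCall:
    strain_id: str
    gene_id: str
    mismatches: int | None
    status: str  # disrupted_exact | disrupted_mismatch | disrupted_larger_cnv |
    #              needs_curation | unedited | low_confidence
    notes: str = ""


def filter_call(
    rec: VariantCallRecord,
    min_reads_exclusive: int = 8,
    max_samples: int = 6,
) -> str:
    """Confidence filter: pass iff strictly more than ``min_reads_exclusive``
    supporting reads AND shared by at most ``max_samples`` samples."""
    if rec.supporting_reads < 0:
        raise ValueError("negative read count")
    if (
        rec.supporting_reads > min_reads_exclusive
        and rec.n_samples_sharing <= max_samples
    ):
        return "pass"
    return "low_confidence"


def compare_to_ssodn(observed: str, design: SsODNDesign) -> int:
    """Mismatch count between the observed locus and the predicted edited
    locus: substituted alignment columns plus gap columns, under a global
    alignment."""
    if len(observed) < 20:
        raise ValueError("window_too_short: observed sequence under 20 nt")
    counts = _aligner.align(design.expected_edited_locus, observed)[0].counts()
    return int(counts.mismatches + counts.gaps)


def classify_allele(
    rec: VariantCallRecord,
    design: SsODNDesign,
    min_reads_exclusive: int = 8,
    max_samples: int = 6,
    max_mismatches: int = 2,
) -> AlleleCall:
    """Classify one allele.

    Order of precedence: the confidence filter, then presence of a variant,
    then the alignment mismatch count m: m = 0 exact; 1 <= m <= 2 mismatch
    repair; m > 2 with a structural flag a larger CNV; m > 2 without flags is
    routed to manual curation.
    """
    if rec.observed_locus_seq and filter_call(rec, min_reads_exclusive, max_samples) != "pass":
        return AlleleCall(rec.strain_id, rec.gene_id, None, "low_confidence",
                          notes=f"reads={rec.supporting_reads}, samples={rec.n_samples_sharing}")
    if not rec.observed_locus_seq:
        return AlleleCall(rec.strain_id, rec.gene_id, None, "unedited",
                          notes="no variant detected at the locus")
    m = compare_to_ssodn(rec.observed_locus_seq, design)
    if m == 0:
        return AlleleCall(rec.strain_id, rec.gene_id, 0, "disrupted_exact")
    if m <= max_mismatches:
        return AlleleCall(rec.strain_id, rec.gene_id, m, "disrupted_mismatch")
    if rec.structural_flags:
        return AlleleCall(
            rec.strain_id, rec.gene_id, m, "disrupted_larger_cnv",
            notes="flags=" + ",".join(sorted(rec.structural_flags)),
        )
    return AlleleCall(rec.strain_id, rec.gene_id, m, "needs_curation",
                      notes="review required: >2 mismatches without structural flags")


def _digest_bands(amplicon: str, site: str) -> list[int]:
    pos = amplicon.find(site)
    if pos < 0:
        return [len(amplicon)]
    cut = pos + len(site) // 2
    return sorted([cut, len(amplicon) - cut])


def insilico_genotype(
    alleles: str | list[str],
    assay: GenotypingAssay,
    design: SsODNDesign,
) -> tuple[str, list[int]]:
    """Simulate the PCR + digest genotyping readout on one or two alleles.

    Each allele must contain both primer landing sites (forward primer
    verbatim and the reverse complement of the reverse primer downstream).
    Returns (call, band_lengths): ``edited`` (two bands), ``wild_type`` (one
    uncut band), or ``heterozygous_like`` (three bands from a mixed pair).
    """
    if isinstance(alleles, str):
        alleles = [alleles]
    site = design.enzyme[1]
    bands: set[int] = set()
    cut_states: set[bool] = set()
    for allele in alleles:
        f = allele.find(assay.fwd_primer)
        rc_rev = reverse_complement(assay.rev_primer)
        r = allele.find(rc_rev, f + 1) if f >= 0 else -1
        if f < 0 or r < 0:
            raise ValueError("primer_dropout: a primer has no landing site")
        amplicon = allele[f : r + len(rc_rev)]
        frags = _digest_bands(amplicon, site)
        bands.update(frags)
        cut_states.add(len(frags) == 2)
    if cut_states == {True}:
        return "edited", sorted(bands)
    if cut_states == {False}:
        return "wild_type", sorted(bands)
    return "heterozygous_like", sorted(bands)
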