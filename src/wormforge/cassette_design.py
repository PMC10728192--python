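"""STOP-IN ssODN repair-template and RFLP genotyping-assay design.

For each target gene the designer picks an SpCas9 cut site in the coding
sequence, builds a single-stranded oligo repair template consisting of two
35-nt homology arms flanking a stop cassette, and designs a PCR/restriction
digest genotyping assay. The cassette simultaneously (i) inserts stop codons
readable in all three frames, (ii) deletes a short stretch of coding sequence
so the net length change is not a multiple of three (frameshift), and (iii)
introduces a restriction site absent from the wild-type amplicon, so edited
loci are identified by a two-band digest while wild-type amplicons stay uncut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GeneModel, Genome, reverse_complement, translate

__all__ = [
    "CutSite",
    "SsODNDesign",
    "GenotypingAssay",
    "DesignParams",
    "DesignError",
    "DEFAULT_ENZYMES",
    "find_cut_sites",
    "design_ssodn",
    "predict_edited_allele",
    "design_genotyping",
    "validate_design",
    "design_gene",
]

# Common 6/8-cutters with unambiguous palindromic recognition sites.
DEFAULT_ENZYMES: list[tuple[str, str]] = [
    ("EcoRI", "GAATTC"),
    ("HindIII", "AAGCTT"),
    ("BamHI", "GGATCC"),
    ("NheI", "GCTAGC"),
    ("XhoI", "CTCGAG"),
    ("SalI", "GTCGAC"),
    ("NotI", "GCGGCCGC"),
    ("PstI", "CTGCAG"),
    ("KpnI", "GGTACC"),
    ("SpeI", "ACTAGT"),
]

# Stop block readable as a stop codon in all three frames:
# TAA(f0) . AAG TAA(f1) . AGT AAG TAA(f2)
_STOP_BLOCK = "TAAGTAAGTAA"
_STOP_TAIL = "TGATAA"


class DesignError(ValueError):
    """A design step failed for one gene; ``code`` is machine-readable."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


@dataclass
class DesignParams:
    del_len: int = 7  # nt removed, centered on the cut (4..30)
    arm_len: int = 35  # "two 35-base homology arms"
    max_ssodn_len: int = 200  # synthesis limit
    amplicon_min: int = 400  # "amplify the fragments of 400 to 1000 bp"
    amplicon_max: int = 1000
    primer_min: int = 18
    primer_max: int = 25
    min_fragment: int = 100  # digest band resolvability
    min_fragment_diff: int = 50
    uniqueness_window: int = 1000  # enzyme pre-check halo around the cut

    def __post_init__(self):
        if not 4 <= self.del_len <= 30:
            raise ValueError("del_len must be in [4, 30]")


@dataclass
class CutSite:
    """An SpCas9 blunt cut: between cut_pos-1 and cut_pos on the reference,
    3 nt 5' of the NGG PAM on the protospacer strand."""

    gene_id: str
    chrom: str
    cut_pos: int
    protospacer: str  # 20 nt, protospacer-strand sequence
    pam: str  # 3 nt, NGG
    strand: str  # strand carrying the protospacer
    cds_offset: int  # nt into the coding sequence
    preferred: bool = False  # lies in the 5' half of the CDS


@dataclass
class SsODNDesign:
    """One gene's repair template and its predicted product."""

    gene_id: str
    cut: CutSite
    left_arm: str
    right_arm: str
    insert_seq: str  # reference-strand sequence placed between the arms
    deleted_interval: tuple[int, int]  # reference coordinates, half-open
    enzyme: tuple[str, str]
    expected_edited_locus: str  # edited region +- flank_len bp
    flank_len: int = 20
    strand: str = "+"  # coding strand of the target gene

    @property
    def ssodn_seq(self) -> str:
        return self.left_arm + self.insert_seq + self.right_arm

    @property
    def net_length_change(self) -> int:
        start, end = self.deleted_interval
        return len(self.insert_seq) - (end - start)

    @property
    def coding_insert(self) -> str:
        """The cassette as read on the coding strand."""
        return self.insert_seq if self.strand == "+" else reverse_complement(self.insert_seq)


@dataclass
class GenotypingAssay:
    """PCR + single-enzyme digest assay distinguishing edited from wild type."""

    gene_id: str
    fwd_primer: str
    rev_primer: str
    amplicon_interval: tuple[int, int]  # wild-type reference coordinates
    wt_amplicon_len: int
    edited_amplicon_len: int
    edited_digest_fragments: list[int]
    wt_digest_fragments: list[int]


def _has_triple_frame_stop(dna: str) -> bool:
    stops = {"TAA", "TAG", "TGA"}
    return all(
        any(dna[i : i + 3] in stops for i in range(frame, len(dna) - 2, 3))
        for frame in range(3)
    )


def find_cut_sites(gene: GeneModel, genome: Genome, pam: str = "NGG") -> list[CutSite]:
    """Scan both strands of the gene's CDS for 20-nt protospacer + NGG sites.

    Results are sorted by cds_offset ascending (earliest truncation first);
    sites whose cut lies in the first half of the CDS are flagged preferred.
    Only cuts falling strictly inside a CDS interval are reported.
    """
    if pam != "NGG":
        raise ValueError("only the SpCas9 NGG PAM is supported")
    if len(gene.cds_seq) < 60:
        raise ValueError(f"gene {gene.gene_id}: CDS shorter than 60 nt")
    chrom_seq = genome[gene.chrom]
    half = len(gene.cds_seq) / 2
    sites: list[CutSite] = []

    def _inside_cds(pos: int) -> bool:
        return any(s < pos < e for s, e in gene.cds_intervals)

    span_start, span_end = gene.cds_span
    lo = max(0, span_start - 25)
    hi = min(len(chrom_seq), span_end + 25)
    region = chrom_seq[lo:hi]
    for i in range(len(region) - 22):
        window = region[i : i + 23]
        # forward protospacer: [i, i+20) + NGG, cut 3 nt 5' of the PAM
        if window[21:23] == "GG":
            cut_pos = lo + i + 17
            off = gene.genomic_to_cds_offset(cut_pos)
            if _inside_cds(cut_pos) and off is not None:
                sites.append(
                    CutSite(
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        cut_pos=cut_pos,
                        protospacer=window[:20],
                        pam=window[20:23],
                        strand="+",
                        cds_offset=off,
                        preferred=False,
                    )
                )
        # reverse protospacer: CCN on the reference at [i, i+3)
        if window[0:2] == "CC":
            cut_pos = lo + i + 6
            off = gene.genomic_to_cds_offset(cut_pos)
            if _inside_cds(cut_pos) and off is not None:
                sites.append(
                    CutSite(
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        cut_pos=cut_pos,
                        protospacer=reverse_complement(window[3:23]),
                        pam=reverse_complement(window[0:3]),
                        strand="-",
                        cds_offset=off,
                        preferred=False,
                    )
                )
    for s in sites:
        s.preferred = s.cds_offset < half
    sites.sort(key=lambda s: (s.cds_offset, s.cut_pos, s.strand))
    return sites


def design_ssodn(
    gene: GeneModel,
    cut: CutSite,
    genome: Genome,
    enzymes: list[tuple[str, str]] | None = None,
    params: DesignParams | None = None,
) -> SsODNDesign:
    """Build the STOP-IN repair template for one cut site.

    The deleted interval (``params.del_len`` nt) is centered on the cut and
    shifted, if needed, to stay within the CDS; the insert is the canonical
    triple-frame stop cassette with the first enzyme site that is absent from
    a +-``uniqueness_window`` halo of the cut in the wild type; arms are
    copied verbatim from the reference flanking the deleted interval.
    """
    enzymes = enzymes or DEFAULT_ENZYMES
    params = params or DesignParams()
    chrom_seq = genome[gene.chrom]

    # deletion interval centered on the cut, clamped into the containing exon
    exon = next(
        ((s, e) for s, e in gene.cds_intervals if s < cut.cut_pos < e), None
    )
    if exon is None:
        raise DesignError("cut_outside_cds", f"cut {cut.cut_pos} not inside CDS")
    del_start = cut.cut_pos - params.del_len // 2 - params.del_len % 2 + 1
    del_end = del_start + params.del_len
    if del_start < exon[0]:
        del_start, del_end = exon[0], exon[0] + params.del_len
    if del_end > exon[1]:
        del_start, del_end = exon[1] - params.del_len, exon[1]
    if del_start < exon[0] or not (del_start < cut.cut_pos <= del_end):
        raise DesignError(
            "cut_near_boundary",
            f"{gene.gene_id}: cannot fit a {params.del_len}-nt deletion "
            f"spanning the cut at {cut.cut_pos}",
        )

    if del_start - params.arm_len < 0 or del_end + params.arm_len > len(chrom_seq):
        raise DesignError("cut_near_boundary", "arm would leave the chromosome")
    left_arm = chrom_seq[del_start - params.arm_len : del_start]
    right_arm = chrom_seq[del_end : del_end + params.arm_len]
    if "N" in left_arm or "N" in right_arm:
        raise DesignError("ambiguous_reference", "N inside a homology arm")

    # halo is a superset of any legal amplicon around this edit
    halo_lo = max(0, cut.cut_pos - params.uniqueness_window - 50)
    halo_hi = min(len(chrom_seq), cut.cut_pos + params.uniqueness_window + 50)
    wt_halo = chrom_seq[halo_lo:halo_hi]

    for name, site in enzymes:
        if site in wt_halo or reverse_complement(site) in wt_halo:
            continue
        cassette = _STOP_BLOCK + site + _STOP_TAIL
        # net length change must not be 0 mod 3; pad with A to reach +1 mod 3
        while (len(cassette) - params.del_len) % 3 != 1:
            cassette += "A"
        insert_ref = cassette if gene.strand == "+" else reverse_complement(cassette)
        edited_window = (
            chrom_seq[max(0, del_start - 40) : del_start]
            + insert_ref
            + chrom_seq[del_end : del_end + 40]
        )
        n_sites = edited_window.count(site) + (
            edited_window.count(reverse_complement(site))
            if reverse_complement(site) != site
            else 0
        )
        if n_sites != 1:
            continue
        flank = 20
        design = SsODNDesign(
            gene_id=gene.gene_id,
            cut=cut,
            left_arm=left_arm,
            right_arm=right_arm,
            insert_seq=insert_ref,
            deleted_interval=(del_start, del_end),
            enzyme=(name, site),
            expected_edited_locus=(
                chrom_seq[del_start - flank : del_start]
                + insert_ref
                + chrom_seq[del_end : del_end + flank]
            ),
            flank_len=flank,
            strand=gene.strand,
        )
        if len(design.ssodn_seq) > params.max_ssodn_len:
            raise DesignError("ssodn_too_long", f"{len(design.ssodn_seq)} nt")
        return design
    raise DesignError(
        "no_unique_site", f"{gene.gene_id}: no enzyme site unique to the edit"
    )


def predict_edited_allele(
    design: SsODNDesign, genome: Genome, flank: int | None = None
) -> str:
    """The edited locus: reference with the deleted interval replaced by the
    insert, returned with ``flank`` bp (default: the design's comparison
    window, 20 bp) of reference on each side."""
    if design.net_length_change == 0 and not design.insert_seq:
        raise DesignError("identity_edit", "no insertion and no deletion")
    flank = design.flank_len if flank is None else flank
    chrom_seq = genome[design.cut.chrom]
    start, end = design.deleted_interval
    return (
        chrom_seq[max(0, start - flank) : start]
        + design.insert_seq
        + chrom_seq[end : end + flank]
    )


def _primer_ok(seq: str) -> bool:
    if "N" in seq:
        return False
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not 0.40 <= gc <= 0.60:
        return False
    run, longest, prev = 0, 0, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        longest = max(longest, run)
    return longest <= 4


def _candidate_primers(
    chrom_seq: str, lo: int, hi: int, params: DesignParams
) -> list[tuple[int, int]]:
    """(start, end) windows in [lo, hi) passing the composition rules."""
    out = []
    for start in range(lo, hi):
        for length in range(params.primer_min, params.primer_max + 1):
            end = start + length
            if end > hi:
                break
            if _primer_ok(chrom_seq[start:end]):
                out.append((start, end))
                break  # first acceptable length at this anchor is enough
    return out


def design_genotyping(
    design: SsODNDesign,
    genome: Genome,
    params: DesignParams | None = None,
) -> GenotypingAssay:
    """Place flanking primers and compute digest fragment sizes.

    Primers are exact reference substrings (18-25 nt, GC 40-60%, no
    mononucleotide run > 4) chosen so the wild-type amplicon is 400-1000 bp
    and the enzyme site splits the edited amplicon into two fragments each
    >= 100 nt and differing by >= 50 nt. The digest cut is modeled at the
    midpoint of the recognition site.
    """
    params = params or DesignParams()
    chrom_seq = genome[design.cut.chrom]
    del_start, del_end = design.deleted_interval
    shift = design.net_length_change

    search = params.amplicon_max
    fwd_lo = max(0, del_start - search)
    fwd_hi = max(0, del_start - 60)
    rev_lo = min(len(chrom_seq), del_end + 60)
    rev_hi = min(len(chrom_seq), del_end + search)
    fwd_cands = _candidate_primers(chrom_seq, fwd_lo, fwd_hi, params)
    rev_cands = _candidate_primers(chrom_seq, rev_lo, rev_hi, params)
    if not fwd_cands or not rev_cands:
        raise DesignError("no_amplicon", f"{design.gene_id}: no primer candidates")

    site = design.enzyme[1]
    any_pair = False
    for f_start, f_end in fwd_cands:
        for r_start, r_end in rev_cands:
            wt_len = r_end - f_start
            if wt_len < params.amplicon_min:
                continue
            if wt_len > params.amplicon_max:
                break  # rev candidates sorted by position; all further too long
            any_pair = True
            edited_amp = (
                chrom_seq[f_start:del_start]
                + design.insert_seq
                + chrom_seq[del_end:r_end]
            )
            pos = edited_amp.find(site)
            if pos < 0 or edited_amp.find(site, pos + 1) >= 0:
                continue
            cut_in_amp = pos + len(site) // 2
            frags = sorted([cut_in_amp, len(edited_amp) - cut_in_amp])
            if frags[0] < params.min_fragment:
                continue
            if frags[1] - frags[0] < params.min_fragment_diff:
                continue
            return GenotypingAssay(
                gene_id=design.gene_id,
                fwd_primer=chrom_seq[f_start:f_end],
                rev_primer=reverse_complement(chrom_seq[r_start:r_end]),
                amplicon_interval=(f_start, r_end),
                wt_amplicon_len=wt_len,
                edited_amplicon_len=wt_len + shift,
                edited_digest_fragments=frags,
                wt_digest_fragments=[wt_len],
            )
    if any_pair:
        raise DesignError(
            "digest_unresolvable",
            f"{design.gene_id}: no placement yields two resolvable fragments",
        )
    raise DesignError("no_amplicon", f"{design.gene_id}: no 400-1000 bp placement")


def validate_design(
    design: SsODNDesign,
    assay: GenotypingAssay,
    genome: Genome,
    gene: GeneModel | None = None,
    params: DesignParams | None = None,
) -> dict:
    """One pass/fail record per design invariant; overall pass iff all pass.

    When the gene model is supplied, the deletion is additionally checked to
    lie within its CDS.
    """
    params = params or DesignParams()
    chrom_seq = genome[design.cut.chrom]
    del_start, del_end = design.deleted_interval
    site = design.enzyme[1]

    wt_amp = chrom_seq[assay.amplicon_interval[0] : assay.amplicon_interval[1]]
    edited_amp = (
        chrom_seq[assay.amplicon_interval[0] : del_start]
        + design.insert_seq
        + chrom_seq[del_end : assay.amplicon_interval[1]]
    )

    checks = {
        "arm_lengths": len(design.left_arm) == params.arm_len
        and len(design.right_arm) == params.arm_len,
        "arms_match_reference": (
            chrom_seq[del_start - params.arm_len : del_start] == design.left_arm
            and chrom_seq[del_end : del_end + params.arm_len] == design.right_arm
        ),
        "frameshift": design.net_length_change % 3 != 0,
        "triple_frame_stops": _has_triple_frame_stop(design.coding_insert),
        "site_unique_in_edited_amplicon": edited_amp.count(site) == 1,
        "site_absent_in_wt_amplicon": site not in wt_amp,
        "deletion_in_cds": gene is None
        or any(s <= del_start and del_end <= e for s, e in gene.cds_intervals),
        "deletion_spans_cut": del_start < design.cut.cut_pos <= del_end,
        "ssodn_length": len(design.ssodn_seq) <= params.max_ssodn_len,
        "wt_amplicon_len": params.amplicon_min
        <= assay.wt_amplicon_len
        <= params.amplicon_max,
        "digest_two_fragments": len(assay.edited_digest_fragments) == 2,
        "fragments_resolvable": (
            len(assay.edited_digest_fragments) == 2
            and min(assay.edited_digest_fragments) >= params.min_fragment
            and abs(
                assay.edited_digest_fragments[1] - assay.edited_digest_fragments[0]
            )
            >= params.min_fragment_diff
        ),
        "wt_uncut": assay.wt_digest_fragments == [assay.wt_amplicon_len],
        "not_identity_edit": len(design.insert_seq) > 0 or del_end > del_start,
    }
    return {"gene_id": design.gene_id, "checks": checks, "pass": all(checks.values())}


def design_gene(
    gene: GeneModel,
    genome: Genome,
    enzymes: list[tuple[str, str]] | None = None,
    params: DesignParams | None = None,
) -> tuple[SsODNDesign, GenotypingAssay]:
    """End-to-end design for one gene: pick the best cut site that yields a
    valid ssODN and genotyping assay (preferred = earliest in the CDS)."""
    params = params or DesignParams()
    sites = find_cut_sites(gene, genome)
    if not sites:
        raise DesignError("no_cut_site", f"{gene.gene_id}: no NGG protospacer in CDS")
    last_err: DesignError | None = None
    for cut in sites:
        try:
            design = design_ssodn(gene, cut, genome, enzymes, params)
            assay = design_genotyping(design, genome, params)
            return design, assay
        except DesignError as err:
            last_err = err
    raise last_err if last_err else DesignError("no_design", gene.gene_id)
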