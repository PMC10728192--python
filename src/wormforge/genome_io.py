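"""Genome and gene-model I/O.

Reads genome FASTA and GFF3 gene models into simple in-memory containers and
provides the coordinate and translation primitives the design and verification
modules build on.

Conventions
-----------
All internal coordinates are 0-based half-open on the reference (+) strand;
conversion to/from 1-based inclusive happens only at the GFF3/BED boundary.
``GeneModel.cds_intervals`` are ordered 5'->3' in gene orientation (descending
reference start for minus-strand genes) and ``cds_seq`` is always the coding
strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GeneModel",
    "GenomeFormatError",
    "GeneModelError",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "translate",
    "reverse_complement",
]

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised for malformed genome FASTA input."""


class GeneModelError(ValueError):
    """Raised when a GFF3 gene model violates the coding-sequence contract."""


def reverse_complement(dna: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, allow_truncation: bool = False) -> str:
    """Translate DNA with the standard genetic code.

    Stop codons render as ``*``; codons containing ambiguity (N) that cannot
    be resolved render as ``X``. Length must be divisible by 3 unless
    ``allow_truncation`` drops the remainder.
    """
    if len(dna) % 3:
        if not allow_truncation:
            raise ValueError(
                f"sequence length {len(dna)} not divisible by 3 "
                "(pass allow_truncation=True to drop the remainder)"
            )
        dna = dna[: len(dna) - len(dna) % 3]
    if not dna:
        return ""
    return str(Seq(dna).translate())


@dataclass
class Genome:
    """A reference genome: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]
    source: str = ""

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence in 0-based half-open coordinates (bounds-checked)."""
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"{chrom}:{start}-{end} outside [0,{len(seq)}]")
        return seq[start:end]


@dataclass
class GeneModel:
    """A protein-coding gene with genomic coordinates, CDS and protein.

    ``cds_intervals`` are (start, end) 0-based half-open on the reference
    strand, ordered 5'->3' in gene orientation; ``cds_seq`` is the spliced
    coding-strand sequence starting with ATG; ``protein`` omits the trailing
    stop.
    """

    gene_id: str
    subfamily: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_seq: str
    protein: str
    transcript_id: str = ""

    @property
    def cds_span(self) -> tuple[int, int]:
        """Reference-strand (min_start, max_end) over all CDS intervals."""
        return (
            min(s for s, _ in self.cds_intervals),
            max(e for _, e in self.cds_intervals),
        )

    def genomic_to_cds_offset(self, pos: int) -> int | None:
        """Map a reference position to its 0-based offset into the coding
        sequence, or None when the position is not inside any CDS interval.

        For a cut boundary ``pos`` (between pos-1 and pos) the returned
        offset is the number of coding nucleotides strictly 5' of the
        boundary in gene orientation.
        """
        offset = 0
        for start, end in self.cds_intervals:
            if self.strand == "+":
                if start <= pos <= end:
                    return offset + (pos - start)
            else:
                if start <= pos <= end:
                    return offset + (end - pos)
            offset += end - start
        return None

    def splice(self, genome: Genome) -> str:
        """Re-extract the coding-strand CDS from the genome (round trip)."""
        parts = []
        for start, end in self.cds_intervals:
            seg = genome.fetch(self.chrom, start, end)
            parts.append(seg if self.strand == "+" else reverse_complement(seg))
        return "".join(parts)


def _validate_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    if "U" in seq:
        raise GenomeFormatError(f"record {name!r}: RNA alphabet (U) not accepted")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise GenomeFormatError(
            f"record {name!r}: non-IUPAC-DNA characters {sorted(bad)}"
        )
    return seq


def read_genome(path: str | Path) -> Genome:
    """Read a genome FASTA; sequences are uppercased and alphabet-checked."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeFormatError(f"duplicate record id {rec.id!r}")
        sequences[rec.id] = _validate_dna(str(rec.seq), rec.id)
    return Genome(sequences=sequences, source=str(path))


def write_genome(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    """Write a genome to FASTA (wrap-normalized round-trip partner)."""
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def _cds_children(db: gffutils.FeatureDB, mrna) -> list:
    return sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)


def read_gene_models(
    gff_path: str | Path,
    genome: Genome,
    subfamily_attr: str = "subfamily",
) -> list[GeneModel]:
    """Build one GeneModel per gene from GFF3 (longest isoform kept).

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open; minus-strand CDS are reverse-complemented and ordered 5'->3'.
    When a gene has several mRNAs, the one with the longest CDS wins, ties
    broken by lexicographically smallest transcript id.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = _cds_children(db, mrna)
            if not cds:
                continue
            total = sum(f.end - f.start + 1 for f in cds)
            candidates.append((-total, mrna.id, mrna, cds))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, transcript_id, mrna, cds = candidates[0]

        gene_id = gene.attributes.get("Name", [gene.id])[0]
        strand = gene.strand
        if strand not in "+-":
            raise GeneModelError(f"gene {gene_id}: strand must be + or -")
        chrom = gene.seqid
        if chrom not in genome:
            raise GeneModelError(f"gene {gene_id}: chromosome {chrom!r} not in genome")
        chrom_len = len(genome[chrom])

        intervals = [(f.start - 1, f.end) for f in cds]  # to 0-based half-open
        for start, end in intervals:
            if not (0 <= start < end <= chrom_len):
                raise GeneModelError(
                    f"gene {gene_id}: CDS interval ({start},{end}) outside "
                    f"chromosome bounds [0,{chrom_len}]"
                )
        for (_, e1), (s2, _) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise GeneModelError(f"gene {gene_id}: overlapping CDS intervals")
        if strand == "-":
            intervals = intervals[::-1]  # 5'->3' in gene orientation

        parts = []
        for start, end in intervals:
            seg = genome.fetch(chrom, start, end)
            parts.append(seg if strand == "+" else reverse_complement(seg))
        cds_seq = "".join(parts)
        if len(cds_seq) % 3:
            raise GeneModelError(
                f"gene {gene_id}: CDS length {len(cds_seq)} not divisible by 3"
            )
        if not cds_seq.startswith("ATG"):
            raise GeneModelError(f"gene {gene_id}: CDS does not start with ATG")
        aa = translate(cds_seq)
        protein = aa[:-1] if aa.endswith("*") else aa
        if "*" in protein:
            raise GeneModelError(f"gene {gene_id}: internal stop codon in CDS")

        subfamily = gene.attributes.get(subfamily_attr, ["NA"])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                subfamily=subfamily,
                chrom=chrom,
                strand=strand,
                cds_intervals=intervals,
                cds_seq=cds_seq,
                protein=protein,
                transcript_id=transcript_id,
            )
        )
    return models
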