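"""Synthetic genomes, editing outcomes and screen data.

Generates every input the pipeline consumes, with the statistical structure
the real study assumes: gene families with a controlled pairwise protein
identity (duplicated receptors diverged by point substitution), a toy genome
and GFF3 with one single-exon gene model per family member, simulated editing
outcomes (perfect repair, repair with planted mismatches, flagged structural
events, unedited loci, and under-supported calls), and behavioral screen
bundles (binomial worm placement, Weibull survival, exponentially bleaching
fluorescence traces with a boxcar stimulus response).

Everything is driven by one integer seed; identical configuration and seed
give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cassette_design import SsODNDesign
from .edit_verification import VariantCallRecord
from .genome_io import GeneModel, Genome, reverse_complement, translate

__all__ = [
    "SimConfig",
    "AMINO_ACIDS",
    "CODON_OF",
    "make_gene_family",
    "build_toy_genome",
    "simulate_edit_outcome",
    "simulate_screen",
    "write_bundle",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# One fixed codon per amino acid: identity targets are defined at the protein
# level, matching the clustering input, so codon usage is irrelevant here.
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGA", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

DEFAULT_EDIT_MODE_MIX = {
    # proportions follow the verified-allele composition of a large knockout
    # library (~82% exact, ~6% small-mismatch, ~12% larger structural events),
    # with small unedited/under-supported mass so every branch is exercised
    "exact": 0.74,
    "mm1": 0.03,
    "mm2": 0.03,
    "mm3plus_flagged": 0.12,
    "unedited": 0.04,
    "under_supported": 0.04,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    n_families: int = 20
    family_size: int = 3
    target_identity: float = 0.60
    ancestor_len_aa: int = 250
    spacer_len: int = 500
    edit_mode_mix: dict = field(default_factory=lambda: dict(DEFAULT_EDIT_MODE_MIX))
    # behavior
    p_attract: float = 0.9
    n_worms: int = 150
    n_plates: int = 3
    p_off_lawn: float = 0.6
    # survival
    wt_mean_days: float = 5.0
    survival_shape: float = 2.0
    effect_multipliers: dict = field(default_factory=dict)
    # fluorescence traces
    bleach_rate: float = 0.02  # 1/s
    trace_amplitude: float = -0.5
    trace_onset_s: float = 60.0
    trace_duration_s: float = 10.0
    trace_total_s: float = 120.0
    trace_dt_s: float = 0.25
    trace_noise_sd: float = 0.01
    trace_baseline: float = 100.0

    def __post_init__(self):
        total = sum(self.edit_mode_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"edit_mode_mix must sum to 1 (got {total})")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(body)


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # never touch the start methionine
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str) -> str:
    """Fixed-codon back-translation with ATG start and a single TAA stop."""
    return "".join(CODON_OF[a] for a in protein) + _STOP


def make_gene_family(
    ancestor_len_aa: int,
    n: int,
    target_identity: float,
    seed: int | np.random.Generator,
) -> tuple[list[str], list[str]]:
    """A family of n proteins: a random ancestor plus n-1 descendants.

    The ancestor is the first member; descendants are produced by
    substituting each non-start site with probability 1 - target_identity,
    so realized pairwise identity to the ancestor concentrates near the
    target for long proteins (the ancestor, being first in name order among
    equal-length members, seeds its family's cluster downstream). Returns
    (proteins, dna) with DNA from the fixed-codon back-translation.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestor = _random_protein(rng, ancestor_len_aa)
    while not _has_5prime_pam(back_translate(ancestor)):
        ancestor = _random_protein(rng, ancestor_len_aa)
    rate = 1.0 - target_identity
    proteins = [ancestor]
    for _ in range(n - 1):
        p = _mutate_protein(rng, ancestor, rate)
        # every emitted CDS must carry a usable protospacer in its 5' half
        while not _has_5prime_pam(back_translate(p)):
            p = _mutate_protein(rng, ancestor, rate)
        proteins.append(p)
    return proteins, [back_translate(p) for p in proteins]


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_toy_genome(
    families: dict[str, list[str]],
    spacer_len: int,
    seed: int | np.random.Generator,
    out_dir: str | Path | None = None,
) -> tuple[Genome, list[GeneModel], str]:
    """Concatenate family genes into one chromosome with random spacers.

    ``families`` maps subfamily name -> list of protein sequences; each gene
    becomes a single-exon plus-strand gene model named
    ``<subfamily>-<index>``. Genes are re-sampled at the codon-silent level
    never (codons are fixed), so a gene whose CDS lacks an NGG protospacer in
    its 5' half is re-rolled with a fresh spacer context; in practice random
    proteins essentially always contain one. Returns (genome, gene models,
    GFF3 text); optionally writes genome.fa / genes.gff3 / proteins.fa to
    ``out_dir``.
    """
    if not families:
        raise ValueError("families must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = "chrI"
    parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    gff_lines = ["##gff-version 3"]

    for subfamily, proteins in families.items():
        for idx, protein in enumerate(proteins, start=1):
            gene_id = f"{subfamily}-{idx}"
            dna = back_translate(protein)
            spacer = _random_spacer(rng, spacer_len)
            parts.append(spacer)
            pos += spacer_len
            start = pos  # 0-based gene start
            end = start + len(dna)
            parts.append(dna)
            pos = end
            if not _has_5prime_pam(dna):
                raise RuntimeError(
                    f"{gene_id}: no NGG protospacer in the 5' half of the CDS"
                )
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    subfamily=subfamily,
                    chrom=chrom,
                    strand="+",
                    cds_intervals=[(start, end)],
                    cds_seq=dna,
                    protein=protein,
                    transcript_id=f"{gene_id}.1",
                )
            )
            attrs = f"ID=gene:{gene_id};Name={gene_id};subfamily={subfamily}"
            gff_lines.append(
                f"{chrom}\twormforge_sim\tgene\t{start + 1}\t{end}\t.\t+\t.\t{attrs}"
            )
            gff_lines.append(
                f"{chrom}\twormforge_sim\tmRNA\t{start + 1}\t{end}\t.\t+\t.\t"
                f"ID=transcript:{gene_id}.1;Parent=gene:{gene_id}"
            )
            gff_lines.append(
                f"{chrom}\twormforge_sim\tCDS\t{start + 1}\t{end}\t.\t+\t0\t"
                f"ID=cds:{gene_id}.1;Parent=transcript:{gene_id}.1"
            )
    parts.append(_random_spacer(rng, spacer_len))
    genome = Genome(sequences={chrom: "".join(parts)}, source="synthetic")
    gff_text = "\n".join(gff_lines) + "\n"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome.fa", "w") as fh:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        (out_dir / "genes.gff3").write_text(gff_text)
        with open(out_dir / "proteins.fa", "w") as fh:
            for m in models:
                fh.write(f">{m.gene_id}\n{m.protein}\n")
        meta = pd.DataFrame(
            {
                "gene_id": [m.gene_id for m in models],
                "subfamily": [m.subfamily for m in models],
                "chrom": [m.chrom for m in models],
                "position": [m.cds_span[0] for m in models],
                "reserved": [False] * len(models),
            }
        )
        meta.to_csv(out_dir / "meta.tsv", sep="\t", index=False)
    return genome, models, gff_text


def _has_5prime_pam(cds: str) -> bool:
    half = len(cds) // 2
    # a usable forward site needs 20 nt of protospacer before the PAM
    for i in range(20, half):
        if cds[i + 1 : i + 3] == "GG":
            return True
        if cds[i - 20 : i - 18] == "CC":
            return True
    return False


EDIT_MODES = ("exact", "mm1", "mm2", "mm3plus_flagged", "unedited", "under_supported")
_FLAGS = ("insertion", "deletion_large", "duplication", "inversion", "complex")


def _plant_substitutions(
    rng: np.random.Generator, seq: str, k: int, window: tuple[int, int]
) -> str:
    lo, hi = window
    positions = rng.choice(np.arange(lo, hi), size=k, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_edit_outcome(
    design: SsODNDesign,
    mode: str,
    seed: int | np.random.Generator,
    strain_id: str = "simstrain",
) -> VariantCallRecord:
    """One simulated caller record for a designed locus.

    exact: the predicted allele verbatim, well supported. mm1/mm2: one/two
    substitutions planted inside the insert-proximal window. mm3plus_flagged:
    at least three substitutions plus a random structural flag. unedited: no
    variant. under_supported: the exact sequence with at most 8 supporting
    reads.
    """
    if mode not in EDIT_MODES:
        raise ValueError(f"unknown edit mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = design.expected_edited_locus
    reads = int(10 + rng.poisson(20))
    samples = 1
    flags: set[str] = set()
    if mode == "exact":
        observed = expected
    elif mode in ("mm1", "mm2"):
        k = 1 if mode == "mm1" else 2
        lo = design.flank_len
        hi = len(expected) - design.flank_len
        observed = _plant_substitutions(rng, expected, k, (lo, hi))
    elif mode == "mm3plus_flagged":
        k = int(rng.integers(3, 9))
        observed = _plant_substitutions(rng, expected, k, (0, len(expected)))
        flags = {_FLAGS[rng.integers(len(_FLAGS))]}
    elif mode == "unedited":
        return VariantCallRecord(strain_id, design.gene_id, "", 0, 1)
    else:  # under_supported
        observed = expected
        reads = int(rng.integers(0, 9))  # <= 8, fails the strict > 8 filter
    return VariantCallRecord(
        strain_id=strain_id,
        gene_id=design.gene_id,
        observed_locus_seq=observed,
        supporting_reads=reads,
        n_samples_sharing=samples,
        structural_flags=flags,
    )


def simulate_screen(
    config: SimConfig,
    strain_ids: list[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate the behavioral screen bundle for a list of strains.

    Returns DataFrames: ``counts`` (quadrant and lawn plate counts per
    replicate), ``survival`` (per-animal survival days), and ``traces``
    (fluorescence time series, one column per strain plus time).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    strain_ids = strain_ids or ["WT"]
    count_rows = []
    survival_rows = []
    trace_cols: dict[str, np.ndarray] = {}
    t = np.arange(0.0, config.trace_total_s, config.trace_dt_s)

    for strain in strain_ids:
        mult = config.effect_multipliers.get(strain, 1.0)
        for rep in range(config.n_plates):
            n_odor = int(rng.binomial(config.n_worms, config.p_attract))
            count_rows.append(
                dict(strain_id=strain, assay="quadrant", replicate=rep,
                     n_odor=n_odor, n_control=config.n_worms - n_odor,
                     n_total=config.n_worms, n_off_lawn=np.nan)
            )
            n_off = int(rng.binomial(config.n_worms, config.p_off_lawn))
            count_rows.append(
                dict(strain_id=strain, assay="lawn", replicate=rep,
                     n_odor=np.nan, n_control=np.nan,
                     n_total=config.n_worms, n_off_lawn=n_off)
            )
        # Weibull mean = scale * Gamma(1 + 1/shape)
        scale = (config.wt_mean_days * mult) / math.gamma(
            1 + 1 / config.survival_shape
        )
        days = scale * rng.weibull(config.survival_shape, size=30)
        survival_rows.extend(
            dict(strain_id=strain, animal=i, days=float(d))
            for i, d in enumerate(days)
        )
        boxcar = (
            (t >= config.trace_onset_s)
            & (t < config.trace_onset_s + config.trace_duration_s)
        ).astype(float)
        y = (
            config.trace_baseline
            * np.exp(-config.bleach_rate * t)
            * (1.0 + config.trace_amplitude * boxcar)
        )
        y = y + rng.normal(0.0, config.trace_noise_sd * config.trace_baseline, t.size)
        trace_cols[strain] = y

    traces = pd.DataFrame({"t": t, **trace_cols})
    return {
        "counts": pd.DataFrame(count_rows),
        "survival": pd.DataFrame(survival_rows),
        "traces": traces,
    }


def write_bundle(
    out_dir: str | Path, config: SimConfig, strain_ids: list[str] | None = None
) -> dict[str, Path]:
    """Write the full synthetic bundle (genome, designs inputs, screen TSVs).

    Every file begins with a comment line recording the seed, so a bundle is
    traceable to its configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    families = {}
    for i in range(config.n_families):
        proteins, _ = make_gene_family(
            config.ancestor_len_aa, config.family_size, config.target_identity, rng
        )
        families[f"fam{i + 1:03d}"] = proteins
    build_toy_genome(families, config.spacer_len, rng, out_dir=out_dir)
    screen = simulate_screen(config, strain_ids, seed=rng)
    paths = {}
    header = f"# seed={config.seed}\n"
    for name, df in screen.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
        paths[name] = path
    return paths
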