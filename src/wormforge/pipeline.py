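"""End-to-end pipeline: group -> design -> verify -> screen.

Chains the library modules over files on disk, with a run manifest recording
tool version, parameters, input/output checksums and timestamp. Per-gene
design failures are data, not exceptions: they are collected into
``errors.tsv`` with machine-readable reason codes, and a run only fails
outright when zero designs succeed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cassette_design import (
    DesignError,
    DesignParams,
    GenotypingAssay,
    SsODNDesign,
    CutSite,
    design_gene,
)
from .edit_verification import VariantCallRecord, classify_allele
from .genome_io import Genome, GeneModel, read_gene_models, read_genome
from .paralog_grouping import (
    GeneMeta,
    GroupingParams,
    ParalogGroup,
    assign_groups,
    cluster_by_identity,
)
from .screen_stats import ScreenRecord, call_hits, chemotaxis_index_quadrant, lawn_indices
from .synthetic_data import SimConfig, simulate_edit_outcome, write_bundle

__all__ = [
    "run_pipeline",
    "write_groups_tsv",
    "write_designs",
    "read_designs_tsv",
    "read_calls_tsv",
    "write_allele_calls_tsv",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_groups_tsv(groups: list[ParalogGroup], meta: dict[str, GeneMeta], path: Path) -> None:
    rows = []
    for grp in groups:
        round_of = {g: i for i, rnd in enumerate(grp.injection_rounds) for g in rnd}
        for g in grp.members:
            rows.append(
                dict(
                    group_id=grp.group_id,
                    gene_id=g,
                    subfamily=meta[g].subfamily,
                    rationale=grp.rationale.get(g, ""),
                    round_index=round_of.get(g, 0),
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_DESIGN_COLS = [
    "gene_id", "chrom", "strand", "cut_pos", "protospacer", "pam", "cut_strand",
    "cds_offset", "enzyme", "enzyme_site", "left_arm", "right_arm", "insert_seq",
    "del_start", "del_end", "ssodn_seq", "expected_edited_locus", "flank_len",
    "fwd_primer", "rev_primer", "amplicon_start", "amplicon_end",
    "wt_amplicon_len", "edited_amplicon_len", "fragment_1", "fragment_2",
]


def write_designs(
    designs: list[tuple[SsODNDesign, GenotypingAssay]], out_dir: Path
) -> None:
    """TSV of designs + ssODN FASTA + BED of deleted intervals."""
    rows = []
    for d, a in designs:
        rows.append(
            dict(
                gene_id=d.gene_id, chrom=d.cut.chrom, strand=d.strand,
                cut_pos=d.cut.cut_pos, protospacer=d.cut.protospacer,
                pam=d.cut.pam, cut_strand=d.cut.strand, cds_offset=d.cut.cds_offset,
                enzyme=d.enzyme[0], enzyme_site=d.enzyme[1],
                left_arm=d.left_arm, right_arm=d.right_arm, insert_seq=d.insert_seq,
                del_start=d.deleted_interval[0], del_end=d.deleted_interval[1],
                ssodn_seq=d.ssodn_seq, expected_edited_locus=d.expected_edited_locus,
                flank_len=d.flank_len, fwd_primer=a.fwd_primer, rev_primer=a.rev_primer,
                amplicon_start=a.amplicon_interval[0], amplicon_end=a.amplicon_interval[1],
                wt_amplicon_len=a.wt_amplicon_len, edited_amplicon_len=a.edited_amplicon_len,
                fragment_1=a.edited_digest_fragments[0],
                fragment_2=a.edited_digest_fragments[1],
            )
        )
    pd.DataFrame(rows, columns=_DESIGN_COLS).to_csv(
        out_dir / "designs.tsv", sep="\t", index=False
    )
    with open(out_dir / "ssodns.fa", "w") as fh:
        for d, _ in designs:
            fh.write(f">{d.gene_id}_ssodn\n{d.ssodn_seq}\n")
    with open(out_dir / "deleted.bed", "w") as fh:
        for d, _ in designs:
            s, e = d.deleted_interval
            fh.write(f"{d.cut.chrom}\t{s}\t{e}\t{d.gene_id}\t0\t{d.strand}\n")


def read_designs_tsv(path: Path) -> list[tuple[SsODNDesign, GenotypingAssay]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        cut = CutSite(
            gene_id=r.gene_id, chrom=r.chrom, cut_pos=int(r.cut_pos),
            protospacer=r.protospacer, pam=r.pam, strand=r.cut_strand,
            cds_offset=int(r.cds_offset),
        )
        d = SsODNDesign(
            gene_id=r.gene_id, cut=cut, left_arm=r.left_arm, right_arm=r.right_arm,
            insert_seq=r.insert_seq, deleted_interval=(int(r.del_start), int(r.del_end)),
            enzyme=(r.enzyme, r.enzyme_site), expected_edited_locus=r.expected_edited_locus,
            flank_len=int(r.flank_len), strand=r.strand,
        )
        a = GenotypingAssay(
            gene_id=r.gene_id, fwd_primer=r.fwd_primer, rev_primer=r.rev_primer,
            amplicon_interval=(int(r.amplicon_start), int(r.amplicon_end)),
            wt_amplicon_len=int(r.wt_amplicon_len),
            edited_amplicon_len=int(r.edited_amplicon_len),
            edited_digest_fragments=[int(r.fragment_1), int(r.fragment_2)],
            wt_digest_fragments=[int(r.wt_amplicon_len)],
        )
        out.append((d, a))
    return out


def read_calls_tsv(path: Path) -> list[VariantCallRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    records = []
    for _, r in df.iterrows():
        flags = set(str(r.structural_flags).split(",")) - {"", "nan"}
        records.append(
            VariantCallRecord(
                strain_id=str(r.strain_id), gene_id=str(r.gene_id),
                observed_locus_seq=str(r.observed_locus_seq),
                supporting_reads=int(r.supporting_reads),
                n_samples_sharing=int(r.n_samples_sharing),
                structural_flags=flags,
            )
        )
    return records


def write_calls_tsv(records: list[VariantCallRecord], path: Path) -> None:
    rows = [
        dict(
            strain_id=r.strain_id, gene_id=r.gene_id,
            observed_locus_seq=r.observed_locus_seq,
            supporting_reads=r.supporting_reads,
            n_samples_sharing=r.n_samples_sharing,
            structural_flags=",".join(sorted(r.structural_flags)),
        )
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_allele_calls_tsv(calls, path: Path) -> None:
    rows = [
        dict(
            strain_id=c.strain_id, gene_id=c.gene_id,
            mismatches="NA" if c.mismatches is None else c.mismatches,
            status=c.status, notes=c.notes, manual_override="",
        )
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages; returns the run manifest.

    ``config`` sections (all optional): ``simulate`` (SimConfig fields; when
    present a synthetic bundle is generated into the output directory and
    used as input), ``inputs`` (genome/gff/meta paths when not simulating),
    ``group``, ``design``, ``verify``, ``screen``. Per-gene design failures
    go to ``errors.tsv``; the manifest's ``n_designs`` reports successes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines: list[str] = []
    errors: list[dict] = []

    def log(stage: str, unit: str, status: str) -> None:
        log_lines.append(f"{stage}\t{unit}\t{status}")

    # --- inputs (simulated or user-provided) ---
    sim_cfg = None
    if "simulate" in config:
        sim_fields = dict(config["simulate"])
        if seed is not None:
            sim_fields["seed"] = seed
        sim_cfg = SimConfig(**sim_fields)
        write_bundle(out_dir, sim_cfg)
        genome_path = out_dir / "genome.fa"
        gff_path = out_dir / "genes.gff3"
        meta_path = out_dir / "meta.tsv"
        log("simulate", "bundle", "ok")
    else:
        inputs = config.get("inputs", {})
        genome_path = Path(inputs["genome"])
        gff_path = Path(inputs["gff"])
        meta_path = Path(inputs["meta"])

    genome = read_genome(genome_path)
    models = read_gene_models(gff_path, genome)
    model_of = {m.gene_id: m for m in models}
    meta_df = pd.read_csv(meta_path, sep="\t", comment="#")
    meta = {
        str(r.gene_id): GeneMeta(
            subfamily=str(r.subfamily), chrom=str(r.chrom),
            position=int(r.position), reserved=bool(r.reserved),
        )
        for _, r in meta_df.iterrows()
    }
    for m in models:
        log("io", m.gene_id, "ok")

    # --- group ---
    gcfg = config.get("group", {})
    threshold = float(gcfg.get("threshold", 0.40))
    gparams = GroupingParams(
        max_group_size=int(gcfg.get("max_group_size", 6)),
        max_per_injection=int(gcfg.get("max_per_injection", 3)),
        linkage_window_bp=int(gcfg.get("linkage_window_bp", 50_000)),
    )
    clusters = cluster_by_identity({m.gene_id: m.protein for m in models}, threshold)
    groups = assign_groups(clusters, meta, gparams)
    write_groups_tsv(groups, meta, out_dir / "groups.tsv")
    for grp in groups:
        log("group", grp.group_id, f"n={len(grp.members)}")

    # --- design ---
    dcfg = config.get("design", {})
    dparams = DesignParams(**{k: v for k, v in dcfg.items() if hasattr(DesignParams(), k)})
    designs: list[tuple[SsODNDesign, GenotypingAssay]] = []
    for m in models:
        try:
            designs.append(design_gene(m, genome, params=dparams))
            log("design", m.gene_id, "ok")
        except DesignError as err:
            errors.append(dict(stage="design", gene_id=m.gene_id, code=err.code,
                               message=str(err)))
            log("design", m.gene_id, f"error:{err.code}")
    write_designs(designs, out_dir)

    # --- verify (simulated outcomes when simulating; else user calls.tsv) ---
    vcfg = config.get("verify", {})
    min_reads = int(vcfg.get("min_reads", 8))
    max_samples = int(vcfg.get("max_samples", 6))
    records: list[VariantCallRecord] = []
    if sim_cfg is not None:
        import numpy as np

        rng = np.random.default_rng(sim_cfg.seed + 1)
        modes = list(sim_cfg.edit_mode_mix)
        probs = [sim_cfg.edit_mode_mix[m] for m in modes]
        for i, (d, _) in enumerate(designs):
            mode = modes[rng.choice(len(modes), p=probs)]
            records.append(
                simulate_edit_outcome(d, mode, rng, strain_id=f"sim{i // 3 + 1:03d}")
            )
        write_calls_tsv(records, out_dir / "calls.tsv")
    elif "calls" in config.get("inputs", {}):
        records = read_calls_tsv(Path(config["inputs"]["calls"]))
    design_of = {d.gene_id: d for d, _ in designs}
    calls = []
    for rec in records:
        if rec.gene_id not in design_of:
            continue
        calls.append(
            classify_allele(rec, design_of[rec.gene_id], min_reads, max_samples)
        )
        log("verify", rec.gene_id, calls[-1].status)
    write_allele_calls_tsv(calls, out_dir / "allele_calls.tsv")

    # --- screen (summaries over the counts table when present) ---
    counts_path = out_dir / "counts.tsv" if sim_cfg is not None else Path(
        config.get("inputs", {}).get("counts", "")
    )
    screen_records: list[ScreenRecord] = []
    if counts_path and counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", comment="#")
        for (strain, assay), sub in counts.groupby(["strain_id", "assay"]):
            if assay == "quadrant":
                cis = [
                    chemotaxis_index_quadrant(int(r.n_odor), int(r.n_control))
                    for _, r in sub.iterrows()
                ]
                screen_records.append(
                    ScreenRecord(strain_id=strain, condition="quadrant",
                                 ci=float(pd.Series(cis).mean()))
                )
            elif assay == "lawn":
                pairs = [
                    lawn_indices(int(r.n_off_lawn), int(r.n_total))
                    for _, r in sub.iterrows()
                ]
                av = float(pd.Series([p[0] for p in pairs]).mean())
                screen_records.append(
                    ScreenRecord(strain_id=strain, condition="lawn",
                                 avoidance=av, occupancy=1 - av)
                )
            log("screen", f"{strain}:{assay}", "ok")
        scfg = config.get("screen", {})
        hits = call_hits(
            [r for r in screen_records if r.ci is not None],
            rule=scfg.get("hit_rule", "repellent_threshold"),
            threshold=float(scfg.get("hit_threshold", -0.5)),
        )
        pd.DataFrame(
            [dict(strain_id=h.strain_id, condition=h.condition, ci=h.ci) for h in hits]
        ).to_csv(out_dir / "hits.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                dict(strain_id=r.strain_id, condition=r.condition, ci=r.ci,
                     avoidance=r.avoidance, occupancy=r.occupancy)
                for r in screen_records
            ]
        ).to_csv(out_dir / "screen_records.tsv", sep="\t", index=False)

    pd.DataFrame(errors, columns=["stage", "gene_id", "code", "message"]).to_csv(
        out_dir / "errors.tsv", sep="\t", index=False
    )
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    outputs = sorted(
        p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "tool": "wormforge",
        "version": __version__,
        "subcommand": "run",
        "parameters": {
            "seed": seed if seed is not None else (sim_cfg.seed if sim_cfg else None),
            "group": {"threshold": threshold, **asdict(gparams)},
            "design": asdict(dparams),
            "verify": {"min_reads": min_reads, "max_samples": max_samples},
        },
        "n_genes": len(models),
        "n_groups": len(groups),
        "n_designs": len(designs),
        "n_design_errors": len(errors),
        "n_allele_calls": len(calls),
        "outputs": {p.name: _sha256(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
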