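# wormforge

A toolkit for building and verifying multiplexed CRISPR knockout libraries of
*C. elegans* chemoreceptor (GPCR) and neuropeptide genes, and for computing
the behavioral statistics used to screen the resulting strains.

Large receptor families are heavily redundant: paralogs that arose by gene
duplication often share a ligand, so single knockouts show no phenotype.
The strategy implemented here disrupts whole paralog groups in single
strains using a STOP-IN single-stranded oligodeoxynucleotide (ssODN) repair
template, then verifies every edited locus from sequencing data and screens
the strains behaviorally. `wormforge` covers that computational workflow end
to end:

- **`genome_io`** — genome FASTA and GFF3 gene models (longest isoform per
  gene), coordinate arithmetic (0-based half-open internally) and
  translation.
- **`paralog_grouping`** — global-alignment protein identity
  (identical positions / shorter length), greedy representative clustering
  at a strict >40% cutoff, and packing of genes into co-editing groups
  (≤6 genes/strain, subfamily-homogeneous) and microinjection rounds
  (≤3 genes/round).
- **`cassette_design`** — SpCas9 cut-site scan (NGG PAM, blunt cut 3 nt 5′
  of the PAM), STOP-IN ssODN design with two 35-nt homology arms flanking a
  cassette that inserts stop codons in all three frames, deletes a short
  coding stretch to force a frameshift, and carries a restriction site
  unique to the edited allele; plus a PCR/digest (RFLP) genotyping assay
  with a 400–1000 bp wild-type amplicon.
- **`edit_verification`** — confidence filtering of variant calls
  (>8 supporting reads, shared by ≤6 samples), pairwise alignment of the
  observed locus (±20 bp flanks) to the predicted edited allele, and
  classification into `disrupted_exact` (0 mismatches),
  `disrupted_mismatch` (≤2), `disrupted_larger_cnv` (flagged structural
  events), `needs_curation`, `unedited`, or `low_confidence`; plus an
  in-silico genotyping readout (digest band patterns).
- **`screen_stats`** — chemotaxis indices
  CI = (N_odor − N_control)/(N_odor + N_control) (quadrant layout) and
  CI = (N_odor − N_control)/N_total (distal-spot layout), single-worm sector
  scores, pathogen-lawn avoidance/occupancy, relative changes vs wild type,
  strict-threshold (CI > −0.5) and quantile hit calling, interval mean
  responses, exponential photobleach correction fit to the first 30 s and
  last 20 s of each recording, ΔF/F₀ with a 5-s pre-onset baseline, and
  cross-condition response correlations for ligand–receptor pairing.
- **`synthetic_data`** — simulated gene families at controlled protein
  identity, toy genomes/GFF3, editing outcomes, and behavioral screens, so
  the whole pipeline runs and is tested without any external data.
- **`pipeline` / `forge` CLI** — one entry point chaining
  group → design → verify → screen with a reproducibility manifest.

## Worked example

```python
import numpy as np
from wormforge import (
    cluster_by_identity, design_gene, pairwise_identity,
    classify_allele, VariantCallRecord,
)
from wormforge.synthetic_data import make_gene_family, build_toy_genome

rng = np.random.default_rng(0)
proteins, _ = make_gene_family(250, 3, 0.6, rng)   # family at ~60% identity
genome, models, _ = build_toy_genome({"srx": proteins}, 500, rng)

print(round(pairwise_identity(models[0].protein, models[1].protein), 3))
print(cluster_by_identity({m.gene_id: m.protein for m in models}, 0.40))

design, assay = design_gene(models[0], genome)
print(len(design.ssodn_seq), design.enzyme, design.deleted_interval)
print(assay.wt_amplicon_len, assay.edited_digest_fragments)

rec = VariantCallRecord("strain1", design.gene_id,
                        design.expected_edited_locus, 25, 1)
print(classify_allele(rec, design).status)
```

prints

```
0.628
[['srx-1', 'srx-2', 'srx-3']]
93 ('EcoRI', 'GAATTC') (504, 511)
607 [105, 518]
disrupted_exact
```

The three family members share ~63% protein identity, so they cluster into
one co-editing group at the >40% cutoff. The ssODN for `srx-1` is 93 nt
(35-nt arm + 23-nt cassette + 35-nt arm), deletes 7 nt around the cut
(net +16 nt, a frameshift) and plants an EcoRI site; the genotyping PCR
gives a 607-bp wild-type band that the edit splits into 105 + 518 bp.
Feeding the predicted edited allele back through verification returns
`disrupted_exact` with 0 mismatches — the round-trip guarantee every design
must satisfy.

The same workflow runs from the shell:

```
forge simulate --seed 1 --out bundle/
forge io validate --genome bundle/genome.fa --gff bundle/genes.gff3
forge group --proteins bundle/proteins.fa --meta bundle/meta.tsv
forge design --genome bundle/genome.fa --gff bundle/genes.gff3 --out designs/
forge run --config run.yaml --out out/ --seed 1
```

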