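"""Protein-identity clustering and co-editing group assignment.

Receptor paralogs are packed into groups destined for a single multiplex-edited
strain: genes sharing >40% protein identity cluster together (greedy
representative clustering, CD-HIT-style shorter-sequence denominator), leftover
genes join groups by chromosomal linkage or by the numeric order of their gene
names, and genes with well-established functions can be reserved as singleton
strains. Each group is then split into microinjection rounds of at most three
genes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "IdentityMatrix",
    "ParalogGroup",
    "GeneMeta",
    "GroupingParams",
    "pairwise_identity",
    "identity_matrix",
    "cluster_by_identity",
    "assign_groups",
    "plan_injections",
]

# Scoring fixed so identity values are reproducible: match +1, mismatch 0,
# first gap column -5, each further gap column -1. Identity counts only
# exact residue matches, divided by the shorter sequence length.
_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two protein sequences.

    Identity = identical aligned positions / length of the shorter sequence
    (the CD-HIT convention); symmetric, in [0, 1].
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    counts = _aligner.align(a, b)[0].counts()
    return counts.identities / min(len(a), len(b))


@dataclass
class IdentityMatrix:
    """Symmetric pairwise-identity matrix over an ordered gene list."""

    gene_ids: list[str]
    identity: np.ndarray

    def lookup(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.identity[i, j])


def identity_matrix(proteins: dict[str, str]) -> IdentityMatrix:
    """All-pairs identity matrix (diagonal 1.0)."""
    ids = list(proteins)
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(proteins[ids[i]], proteins[ids[j]])
    return IdentityMatrix(gene_ids=ids, identity=mat)


def cluster_by_identity(
    proteins: dict[str, str], threshold: float = 0.40
) -> list[list[str]]:
    """Greedy representative clustering at a strict identity threshold.

    Genes are visited by protein length descending (ties broken by gene id);
    each joins the first existing cluster whose *representative* (the seed,
    the longest member) has identity strictly above the threshold, otherwise
    it seeds a new cluster. Deterministic and independent of input ordering.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    clusters: list[list[str]] = []
    representatives: list[str] = []
    for gene in order:
        for ci, rep in enumerate(representatives):
            if pairwise_identity(proteins[gene], proteins[rep]) > threshold:
                clusters[ci].append(gene)
                break
        else:
            clusters.append([gene])
            representatives.append(gene)
    return clusters


@dataclass
class GeneMeta:
    """Grouping metadata for one gene."""

    subfamily: str
    chrom: str
    position: int  # representative locus coordinate (0-based)
    reserved: bool = False


@dataclass
class GroupingParams:
    max_group_size: int = 6  # "maximum of 2 rounds of editing (<=6 genes)"
    max_per_injection: int = 3  # "Up to 3 genes were targeted in each microinjection"
    linkage_window_bp: int = 50_000  # "closely linked" is unquantified; configurable
    hard_cap: bool = True  # split identity clusters larger than max_group_size


@dataclass
class ParalogGroup:
    """A set of genes destined for one strain."""

    group_id: str
    members: list[str]
    rationale: dict[str, str] = field(default_factory=dict)
    injection_rounds: list[list[str]] = field(default_factory=list)


_NUMERIC_RE = re.compile(r"^(.*?)(\d+)\D*$")


def _numeric_key(gene_id: str) -> tuple[str, int]:
    """Sort key implementing 'numerical orders of gene names' (srx-2 < srx-10)."""
    m = _NUMERIC_RE.match(gene_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (gene_id, 0)


def plan_injections(group: ParalogGroup, max_per_injection: int = 3) -> ParalogGroup:
    """Partition members, in listed order, into rounds of <= max_per_injection."""
    group.injection_rounds = [
        group.members[i : i + max_per_injection]
        for i in range(0, len(group.members), max_per_injection)
    ]
    return group


def assign_groups(
    clusters: list[list[str]],
    metadata: dict[str, GeneMeta],
    params: GroupingParams | None = None,
    phylogeny_pairs: dict[str, str] | None = None,
) -> list[ParalogGroup]:
    """Pack clustered genes into co-editing groups under the strain constraints.

    Stages, in order:

    1. identity clusters become seed groups, split in cluster order into
       chunks of <= max_group_size (rationale ``identity``);
    2. remaining singletons within ``linkage_window_bp`` of a same-subfamily
       group member on the same chromosome join that group if capacity allows
       (``linkage``);
    3. singletons named in ``phylogeny_pairs`` (a user-supplied tree-derived
       pairing table) join their partner's group if compatible
       (``phylogeny_stub``);
    4. leftovers are packed by numeric order of gene names within each
       subfamily (``numeric_order``);
    5. genes flagged reserved always become singleton groups
       (``reserved_singleton``).

    Subfamily homogeneity is enforced throughout: clusters that mix
    subfamilies are split by subfamily before packing.
    """
    params = params or GroupingParams()
    phylogeny_pairs = phylogeny_pairs or {}
    all_genes = [g for c in clusters for g in c]
    missing = [g for g in all_genes if g not in metadata]
    if missing:
        raise ValueError(f"genes missing metadata: {missing}")

    groups: list[ParalogGroup] = []
    singles: list[str] = []

    def new_group(members: list[str], tag: str) -> ParalogGroup:
        grp = ParalogGroup(
            group_id=f"group{len(groups) + 1:04d}",
            members=list(members),
            rationale={g: tag for g in members},
        )
        groups.append(grp)
        return grp

    # reserved genes come out first, regardless of clustering
    reserved = [g for g in all_genes if metadata[g].reserved]
    for cluster in clusters:
        res_in = [g for g in cluster if metadata[g].reserved]
        if res_in and len(cluster) > 1:
            warnings.warn(
                f"reserved gene(s) {res_in} removed from a {len(cluster)}-member "
                "identity cluster and forced singleton"
            )

    # stage 1: identity clusters -> seed groups (subfamily-split, size-capped)
    for cluster in clusters:
        members = [g for g in cluster if not metadata[g].reserved]
        by_subfam: dict[str, list[str]] = {}
        for g in members:
            by_subfam.setdefault(metadata[g].subfamily, []).append(g)
        for sub_members in by_subfam.values():
            if len(sub_members) == 1:
                singles.append(sub_members[0])
                continue
            if params.hard_cap:
                for i in range(0, len(sub_members), params.max_group_size):
                    new_group(sub_members[i : i + params.max_group_size], "identity")
            else:
                new_group(sub_members, "identity")

    # stage 2: linkage rescue of singletons
    still_single: list[str] = []
    for g in singles:
        meta = metadata[g]
        joined = False
        for grp in groups:
            if len(grp.members) >= params.max_group_size:
                continue
            for member in grp.members:
                m = metadata[member]
                if (
                    m.subfamily == meta.subfamily
                    and m.chrom == meta.chrom
                    and abs(m.position - meta.position) <= params.linkage_window_bp
                ):
                    grp.members.append(g)
                    grp.rationale[g] = "linkage"
                    joined = True
                    break
            if joined:
                break
        if not joined:
            still_single.append(g)

    # stage 3: phylogeny-derived pairing (stub: user-supplied table)
    leftovers: list[str] = []
    for g in still_single:
        partner = phylogeny_pairs.get(g)
        joined = False
        if partner:
            for grp in groups:
                if (
                    partner in grp.members
                    and len(grp.members) < params.max_group_size
                    and metadata[partner].subfamily == metadata[g].subfamily
                ):
                    grp.members.append(g)
                    grp.rationale[g] = "phylogeny_stub"
                    joined = True
                    break
        if not joined:
            leftovers.append(g)

    # stage 4: numeric-order packing within subfamily
    by_subfam: dict[str, list[str]] = {}
    for g in leftovers:
        by_subfam.setdefault(metadata[g].subfamily, []).append(g)
    for subfamily in sorted(by_subfam):
        ordered = sorted(by_subfam[subfamily], key=_numeric_key)
        for i in range(0, len(ordered), params.max_group_size):
            new_group(ordered[i : i + params.max_group_size], "numeric_order")

    # stage 5: reserved singletons
    for g in sorted(reserved, key=_numeric_key):
        new_group([g], "reserved_singleton")

    for grp in groups:
        plan_injections(grp, params.max_per_injection)
    return groups
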