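"""Greedy centroid-based ortholog clustering and the presence matrix.

Proteins from all genomes are swept once in decreasing length order
(ties broken by id); each protein joins the first existing centroid it
matches at the identity/coverage thresholds, otherwise it founds a new
cluster.  This is the classic greedy incremental scheme (UCLUST/CD-HIT
style) and is fully deterministic for a given input set regardless of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import PROTEIN_SCORING, KmerIndex, ScoringScheme, align_local
from .io import MetadataTable, ProteinRecord

#: k-mer length used to shortlist candidate centroids.
PRESCREEN_K = 4


@dataclass(frozen=True)
class GeneCluster:
    """An orthologous protein family: a centroid plus its members."""

    cluster_id: str
    centroid: str
    members: tuple[tuple[str, str], ...]  # (genome_id, protein_id)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


def cluster_proteins(
    proteins: list[ProteinRecord],
    identity_threshold: float = 0.5,
    coverage_threshold: float = 0.8,
    scoring: ScoringScheme = PROTEIN_SCORING,
) -> list[GeneCluster]:
    """Cluster proteins from all genomes into orthologous families.

    A protein joins the earliest-founded centroid whose local alignment
    reaches ``identity_threshold`` (over alignment columns) and covers at
    least ``coverage_threshold`` of the shorter of the two sequences.
    Candidate centroids are shortlisted by shared 4-mers; a centroid
    sharing no 4-mer with the query cannot plausibly reach the 50%
    identity floor and is skipped.

    The 50% identity default mirrors the common default of pan-genome
    clustering tools; the coverage floor prevents domain-sharing
    chaining.  Both are configurable.
    """
    if not proteins:
        raise ValueError("cluster_proteins: no input proteins")
    if not 0 < identity_threshold <= 1 or not 0 < coverage_threshold <= 1:
        raise ValueError("thresholds must lie in (0, 1]")

    ordered = sorted(proteins, key=lambda p: (-p.length, p.protein_id))
    centroid_seqs: dict[str, str] = {}
    centroid_order: dict[str, int] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    index = KmerIndex({}, PRESCREEN_K)

    for prot in ordered:
        assigned = None
        # short sequences share few k-mers even with near-identical
        # centroids; demand more sharing from long ones to keep the
        # candidate list tight
        min_shared = 1 if prot.length < 30 else 3
        candidates = index.query(prot.sequence, min_shared=min_shared)
        # first-fit in centroid creation order
        for cid in sorted(candidates, key=centroid_order.__getitem__):
            aln = align_local(prot.sequence, centroid_seqs[cid], scoring)
            shorter = min(prot.length, len(centroid_seqs[cid]))
            aligned_shorter = min(
                aln.query_span[1] - aln.query_span[0],
                aln.target_span[1] - aln.target_span[0],
            )
            if (
                aln.identity >= identity_threshold
                and aligned_shorter / shorter >= coverage_threshold
            ):
                assigned = cid
                break
        if assigned is None:
            assigned = prot.protein_id
            centroid_seqs[assigned] = prot.sequence
            centroid_order[assigned] = len(centroid_order)
            members[assigned] = []
            index.add(assigned, prot.sequence)
        members[assigned].append((prot.genome_id, prot.protein_id))

    width = max(5, len(str(len(members))))
    clusters = []
    for i, (centroid, mem) in enumerate(
        sorted(members.items(), key=lambda kv: centroid_order[kv[0]])
    ):
        clusters.append(
            GeneCluster(
                cluster_id=f"GC{i + 1:0{width}d}",
                centroid=centroid,
                members=tuple(mem),
            )
        )
    return clusters


def build_presence_matrix(
    clusters: list[GeneCluster], metadata: MetadataTable
) -> pd.DataFrame:
    """Boolean cluster-by-genome occurrence matrix.

    A cell is True when the cluster has at least one member from that
    genome (paralogs collapse to a single presence).  Rows are sorted by
    cluster id and columns by genome id, so the matrix is deterministic.
    """
    genome_ids = sorted(metadata.genome_ids)
    known = set(genome_ids)
    for cluster in clusters:
        missing = cluster.genomes - known
        if missing:
            raise ValueError(
                f"cluster {cluster.cluster_id}: genome(s) {sorted(missing)} "
                "absent from metadata"
            )
    rows = sorted(clusters, key=lambda c: c.cluster_id)
    data = {
        c.cluster_id: [g in c.genomes for g in genome_ids] for c in rows
    }
    matrix = pd.DataFrame.from_dict(
        data, orient="index", columns=genome_ids
    )
    matrix.index.name = "cluster_id"
    return matrix


def write_membership(clusters: list[GeneCluster], path) -> None:
    """Write cluster membership as TSV (cluster_id, genome_id, protein_id)."""
    recs = [
        (c.cluster_id, g, p)
        for c in sorted(clusters, key=lambda c: c.cluster_id)
        for g, p in c.members
    ]
    pd.DataFrame(recs, columns=["cluster_id", "genome_id", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )
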