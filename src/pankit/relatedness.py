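"""Pairwise genome relatedness indices: ANI, AAI and POCP.

ANI follows the fragment-based (ANIb-style) recipe: the query genome is
cut into fixed-width fragments, each fragment is mapped to its best
local alignment in the subject (both strands), and the mean identity of
the retained fragments is reported, symmetrised over both directions.
AAI is the mean identity of reciprocal-best-hit protein pairs, and POCP
is the percentage of conserved proteins under E-value/identity/coverage
filters.  Interpretation thresholds: ANI >= 95% same species, AAI >= 65%
and POCP >= 50% same genus.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .align import (
    NUCLEOTIDE_SCORING,
    PROTEIN_SCORING,
    KmerIndex,
    ScoringScheme,
    align_local,
    evalue,
)
from .io import GenomeRecord, ProteinRecord

ANI_SPECIES_THRESHOLD = 95.0
AAI_GENUS_THRESHOLD = 65.0
POCP_GENUS_THRESHOLD = 50.0

#: k-mer length of the genome fragment-mapping index.
GENOME_INDEX_K = 14
#: window margin (bp) around the voted fragment location.
WINDOW_MARGIN = 150
#: candidate best-hit targets examined per protein query.
MAX_PROTEIN_CANDIDATES = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RelatednessResult:
    """A pairwise relatedness value plus its supporting evidence count.

    ``value`` is a percentage (0-100) or ``None`` when undefined (no
    retained fragments / no reciprocal best hits); ``n_support`` counts
    the retained fragments, RBH pairs, or conserved proteins.
    """

    genome_a: str
    genome_b: str
    metric: str  # "ANI" | "AAI" | "POCP"
    value: float | None
    n_support: int

    @property
    def same_species(self) -> bool:
        return (
            self.metric == "ANI"
            and self.value is not None
            and self.value >= ANI_SPECIES_THRESHOLD
        )

    @property
    def same_genus_aai(self) -> bool:
        return (
            self.metric == "AAI"
            and self.value is not None
            and self.value >= AAI_GENUS_THRESHOLD
        )

    @property
    def same_genus_pocp(self) -> bool:
        return (
            self.metric == "POCP"
            and self.value is not None
            and self.value >= POCP_GENUS_THRESHOLD
        )


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

class _FragmentLocator:
    """k-mer position index of one genome for fragment mapping.

    Fragment placement is estimated by diagonal voting: every shared
    k-mer votes for the offset (target position - query position), and
    the modal offset locates the window to align against.
    """

    def __init__(self, sequence: str, k: int = GENOME_INDEX_K):
        self.sequence = sequence
        self.k = k
        self._positions: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            self._positions.setdefault(sequence[i : i + k], []).append(i)

    def vote(self, fragment: str) -> tuple[int, int]:
        """Best (offset, n_votes) for a fragment on the indexed strand."""
        votes: Counter[int] = Counter()
        k = self.k
        for i in range(len(fragment) - k + 1):
            for j in self._positions.get(fragment[i : i + k], ()):
                votes[j - i] += 1
        if not votes:
            return 0, 0
        offset, n = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        return offset, n


def _directed_ani(
    query: str,
    locator: _FragmentLocator,
    fragment_bp: int,
    min_identity: float,
    min_coverage: float,
    scoring: ScoringScheme,
) -> tuple[list[float], int]:
    """Identities of retained fragments of ``query`` mapped onto the target."""
    identities: list[float] = []
    target = locator.sequence
    n_fragments = len(query) // fragment_bp  # trailing fragment dropped
    for f in range(n_fragments):
        fragment = query[f * fragment_bp : (f + 1) * fragment_bp]
        fwd_off, fwd_votes = locator.vote(fragment)
        rc = reverse_complement(fragment)
        rev_off, rev_votes = locator.vote(rc)
        if fwd_votes == 0 and rev_votes == 0:
            continue
        piece = fragment if fwd_votes >= rev_votes else rc
        offset = fwd_off if fwd_votes >= rev_votes else rev_off
        lo = max(0, offset - WINDOW_MARGIN)
        hi = min(len(target), offset + fragment_bp + WINDOW_MARGIN)
        window = target[lo:hi]
        if not window:
            continue
        aln = align_local(piece, window, scoring)
        if aln.identity >= min_identity and aln.query_coverage >= min_coverage:
            identities.append(aln.identity)
    return identities, n_fragments


def ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_bp: int = 1020,
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
    scoring: ScoringScheme = NUCLEOTIDE_SCORING,
) -> RelatednessResult:
    """Fragment-based average nucleotide identity, symmetrised.

    Each direction cuts one genome into consecutive ``fragment_bp``
    pieces (the short trailing piece is dropped), aligns each piece to
    its best location on either strand of the other genome, and keeps
    fragments with identity >= ``min_identity`` and fragment coverage >=
    ``min_coverage``.  The reported ANI is the mean of the two directed
    mean identities, as a percentage.
    """
    if len(a) < fragment_bp or len(b) < fragment_bp:
        raise ValueError(f"both genomes must be at least fragment_bp={fragment_bp} long")
    ids_ab, _ = _directed_ani(
        a.sequence, _FragmentLocator(b.sequence), fragment_bp,
        min_identity, min_coverage, scoring,
    )
    ids_ba, _ = _directed_ani(
        b.sequence, _FragmentLocator(a.sequence), fragment_bp,
        min_identity, min_coverage, scoring,
    )
    n_support = len(ids_ab) + len(ids_ba)
    if not ids_ab or not ids_ba:
        return RelatednessResult(a.genome_id, b.genome_id, "ANI", None, n_support)
    value = 100.0 * (
        (sum(ids_ab) / len(ids_ab)) + (sum(ids_ba) / len(ids_ba))
    ) / 2.0
    return RelatednessResult(a.genome_id, b.genome_id, "ANI", value, n_support)


# ---------------------------------------------------------------------------
# AAI / POCP
# ---------------------------------------------------------------------------

def _best_hit(
    query: ProteinRecord,
    targets: dict[str, ProteinRecord],
    index: KmerIndex,
    db_residues: int,
    min_identity: float,
    min_coverage: float,
    max_evalue: float,
    coverage_of: str,
    scoring: ScoringScheme,
) -> tuple[str, float] | None:
    """Highest-scoring target passing the filters, or None.

    ``coverage_of`` selects the coverage denominator: ``"shorter"`` (AAI
    convention) or ``"query"`` (POCP convention).
    """
    best: tuple[float, str, float] | None = None
    candidates = index.query(query.sequence, min_shared=1)[:MAX_PROTEIN_CANDIDATES]
    for tid in candidates:
        target = targets[tid]
        aln = align_local(query.sequence, target.sequence, scoring)
        if aln.score <= 0:
            continue
        if coverage_of == "shorter":
            cov = (
                aln.query_coverage
                if len(query) <= len(target)
                else aln.target_coverage
            )
        else:
            cov = aln.query_coverage
        if aln.identity < min_identity or cov < min_coverage:
            continue
        if evalue(aln.score, len(query), db_residues, scoring) > max_evalue:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, tid, aln.identity)
    if best is None:
        return None
    return best[1], best[2]


def _proteome_index(proteome: list[ProteinRecord]) -> tuple[dict[str, ProteinRecord], KmerIndex, int]:
    by_id = {p.protein_id: p for p in proteome}
    if len(by_id) != len(proteome):
        raise ValueError("duplicate protein ids within a proteome")
    index = KmerIndex({pid: p.sequence for pid, p in by_id.items()}, k=4)
    return by_id, index, sum(len(p) for p in proteome)


def aai(
    a: list[ProteinRecord],
    b: list[ProteinRecord],
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
    max_evalue: float = 1e-3,
    scoring: ScoringScheme = PROTEIN_SCORING,
) -> RelatednessResult:
    """Average amino-acid identity over reciprocal best-hit pairs.

    Best hits are searched in both directions under the identity /
    coverage-of-the-shorter-sequence / E-value filters; pairs that are
    each other's best hit are retained and their mean identity reported
    as a percentage.  Zero RBHs yields an undefined result.
    """
    if not a or not b:
        raise ValueError("aai: empty proteome")
    genome_a, genome_b = a[0].genome_id, b[0].genome_id
    by_a, idx_a, res_a = _proteome_index(a)
    by_b, idx_b, res_b = _proteome_index(b)
    hits_ab = {}
    for prot in a:
        hit = _best_hit(
            prot, by_b, idx_b, res_b, min_identity, min_coverage,
            max_evalue, "shorter", scoring,
        )
        if hit:
            hits_ab[prot.protein_id] = hit
    hits_ba = {}
    for prot in b:
        hit = _best_hit(
            prot, by_a, idx_a, res_a, min_identity, min_coverage,
            max_evalue, "shorter", scoring,
        )
        if hit:
            hits_ba[prot.protein_id] = hit
    rbh_identities = [
        identity
        for qid, (tid, identity) in hits_ab.items()
        if hits_ba.get(tid, (None,))[0] == qid
    ]
    if not rbh_identities:
        return RelatednessResult(genome_a, genome_b, "AAI", None, 0)
    value = 100.0 * sum(rbh_identities) / len(rbh_identities)
    return RelatednessResult(genome_a, genome_b, "AAI", value, len(rbh_identities))


def pocp(
    a: list[ProteinRecord],
    b: list[ProteinRecord],
    max_evalue: float = 1e-5,
    min_identity: float = 0.4,
    min_query_coverage: float = 0.5,
    scoring: ScoringScheme = PROTEIN_SCORING,
) -> RelatednessResult:
    """Percentage of conserved proteins: 100 * (C1 + C2) / (T1 + T2).

    C1 counts proteins of ``a`` with at least one hit in ``b`` passing
    the E-value, identity and query-coverage filters; C2 is symmetric.
    Zero is a valid value when nothing is conserved.
    """
    if not a or not b:
        raise ValueError("pocp: empty proteome")
    genome_a, genome_b = a[0].genome_id, b[0].genome_id
    by_a, idx_a, res_a = _proteome_index(a)
    by_b, idx_b, res_b = _proteome_index(b)
    c1 = sum(
        1
        for prot in a
        if _best_hit(
            prot, by_b, idx_b, res_b, min_identity, min_query_coverage,
            max_evalue, "query", scoring,
        )
    )
    c2 = sum(
        1
        for prot in b
        if _best_hit(
            prot, by_a, idx_a, res_a, min_identity, min_query_coverage,
            max_evalue, "query", scoring,
        )
    )
    value = 100.0 * (c1 + c2) / (len(a) + len(b))
    return RelatednessResult(genome_a, genome_b, "POCP", value, c1 + c2)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def relatedness_matrix(results: list[RelatednessResult]) -> pd.DataFrame:
    """Square symmetric matrix from a list of same-metric pairwise results."""
    metrics = {r.metric for r in results}
    if len(metrics) != 1:
        raise ValueError(f"mixed metrics in one matrix: {sorted(metrics)}")
    ids = sorted({r.genome_a for r in results} | {r.genome_b for r in results})
    mat = pd.DataFrame(float("nan"), index=ids, columns=ids)
    for gid in ids:
        mat.loc[gid, gid] = 100.0
    for r in results:
        val = math.nan if r.value is None else r.value
        mat.loc[r.genome_a, r.genome_b] = val
        mat.loc[r.genome_b, r.genome_a] = val
    mat.index.name = "id"
    return mat
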