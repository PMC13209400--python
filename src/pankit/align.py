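"""Shared pairwise-alignment machinery.

Local (Smith-Waterman) alignment with affine gap penalties, identity and
coverage bookkeeping, a k-mer candidate prescreen, and Karlin-Altschul
E-values.  All of the relatedness indices (ANI, AAI, POCP) and the
ortholog clustering are built on this one engine, so every downstream
identity figure shares a single, fixed convention: identity is counted
over all alignment columns, internal gap columns included.

The dynamic programming itself is delegated to Bio.Align.PairwiseAligner
(an exact affine-gap Smith-Waterman in C); this module owns the scoring
conventions and the derived statistics.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin-Altschul constants.

    ``matrix_name`` selects a named amino-acid substitution matrix
    (e.g. BLOSUM62); when None, ``match``/``mismatch`` scores are used
    (nucleotide mode).  ``lam`` and ``K`` parameterise the E-value
    E = K * m * n * exp(-lam * S).
    """

    alphabet: str  # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -2
    matrix_name: str | None = None
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if abs(self.gap_extend) > abs(self.gap_open):
            raise ValueError("gap_extend must not cost more than gap_open")


#: Default nucleotide scoring: match +1 / mismatch -2, affine -5/-2.
NUCLEOTIDE_SCORING = ScoringScheme(
    alphabet="nucleotide", match=1, mismatch=-2,
    gap_open=-5, gap_extend=-2, lam=1.28, K=0.46,
)

#: Default protein scoring: BLOSUM62, affine -11/-1, standard gapped
#: Karlin-Altschul constants.
PROTEIN_SCORING = ScoringScheme(
    alphabet="protein", matrix_name="BLOSUM62",
    gap_open=-11, gap_extend=-1, lam=0.267, K=0.041,
)


@dataclass(frozen=True)
class PairwiseAlignment:
    """One local alignment with its identity/coverage statistics."""

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    score: float
    n_columns: int
    n_matches: int
    identity: float
    query_coverage: float
    target_coverage: float


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.matrix_name is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_local(
    a: str,
    b: str,
    scoring: ScoringScheme,
    query_id: str = "query",
    target_id: str = "target",
) -> PairwiseAlignment:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    Identity is ``n_matches / n_columns`` where columns include internal
    gap columns (a gapped column counts as a mismatch).  Coverage is the
    number of aligned residues of a sequence divided by its full length.
    Tie-breaking among equal-scoring optima is deterministic (the first
    traceback reported by the engine).
    """
    if not a or not b:
        raise ValueError("align_local: empty sequence")
    aligner = _aligner(scoring)
    try:
        alignment = next(iter(aligner.align(a, b)))
    except StopIteration:
        # no positive-scoring local alignment exists
        return PairwiseAlignment(
            query_id=query_id, target_id=target_id,
            query_span=(0, 0), target_span=(0, 0), score=0.0,
            n_columns=0, n_matches=0, identity=0.0,
            query_coverage=0.0, target_coverage=0.0,
        )
    counts = alignment.counts()
    n_matches = counts.identities
    n_columns = counts.identities + counts.mismatches + counts.internal_gaps
    q_segments, t_segments = alignment.aligned[0], alignment.aligned[1]
    q_res = int(sum(e - s for s, e in q_segments))
    t_res = int(sum(e - s for s, e in t_segments))
    q_span = (int(q_segments[0][0]), int(q_segments[-1][1])) if len(q_segments) else (0, 0)
    t_span = (int(t_segments[0][0]), int(t_segments[-1][1])) if len(t_segments) else (0, 0)
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        query_span=q_span,
        target_span=t_span,
        score=float(alignment.score),
        n_columns=n_columns,
        n_matches=n_matches,
        identity=n_matches / n_columns if n_columns else 0.0,
        query_coverage=q_res / len(a),
        target_coverage=t_res / len(b),
    )


# ---------------------------------------------------------------------------
# k-mer prescreen
# ---------------------------------------------------------------------------

def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


class KmerIndex:
    """Per-target k-mer sets for repeated prescreen queries."""

    def __init__(self, targets: dict[str, str], k: int):
        if k < 4:
            raise ValueError("kmer prescreen requires k >= 4")
        self.k = k
        self._sets = {tid: _kmers(seq, k) for tid, seq in targets.items()}
        self._order = list(targets)

    def add(self, target_id: str, sequence: str) -> None:
        """Add one more target to the index (used by incremental clustering)."""
        self._sets[target_id] = _kmers(sequence, self.k)
        self._order.append(target_id)

    def query(self, sequence: str, min_shared: int = 1) -> list[str]:
        """Target ids sharing >= min_shared k-mers with the query.

        Ranked by decreasing shared-k-mer count; ties keep index
        insertion order.  ``min_shared == 0`` returns every target.
        """
        qset = _kmers(sequence, self.k)
        scored = []
        for pos, tid in enumerate(self._order):
            shared = len(qset & self._sets[tid])
            if shared >= min_shared:
                scored.append((-shared, pos, tid))
        scored.sort()
        return [tid for _, _, tid in scored]


def kmer_prescreen(
    query: str, targets: dict[str, str], k: int, min_shared: int = 1
) -> list[str]:
    """One-shot candidate screen; see :class:`KmerIndex` for repeated use."""
    return KmerIndex(targets, k).query(query, min_shared)


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------

def evalue(score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S).

    An explicit approximation of BLAST's statistics; the downstream
    thresholds that consume it are configurable, so the filters rather
    than the exact E carry the semantics.
    """
    if m <= 0 or n <= 0:
        raise ValueError("evalue: sequence/database lengths must be positive")
    if score <= 0:
        raise ValueError("evalue: score must be positive")
    return scoring.K * m * n * math.exp(-scoring.lam * score)
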