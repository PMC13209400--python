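"""Descriptive genome statistics: GC content, coding density, interval spans.

The arithmetic conventions here (rounding, interval length, GC
denominator) are fixed so that the same printed inputs always reproduce
the same printed summaries; see the methods note for the rationale
behind each convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .io import GenomeRecord


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (4.5 -> 5), unlike banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class GenomeSummary:
    """Per-genome descriptive statistics."""

    genome_id: str
    length_bp: int
    gc_percent: float
    n_orfs: int
    total_orf_bp: int
    coding_percent: float
    mean_gene_length_bp: int


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence, to 2 decimals.

    The denominator is the full sequence length including ambiguous (N)
    bases, matching the usual assembly-report convention.
    """
    if not sequence:
        raise ValueError("gc_content: empty sequence")
    gc = sequence.count("G") + sequence.count("C")
    return _round_half_up(100.0 * gc / len(sequence), 2)


def coding_statistics(
    total_orf_bp: int, n_orfs: int, genome_length_bp: int
) -> tuple[float, int]:
    """Coding fraction (%) and mean gene length (bp) from ORF totals.

    Returns ``(coding_percent, mean_gene_length_bp)`` where the coding
    percentage is rounded to 2 decimals and the mean gene length to the
    nearest integer.  Overlapping ORFs can push the coding total past the
    genome length; that case warns rather than fails.
    """
    if n_orfs <= 0:
        raise ValueError("coding_statistics: n_orfs must be positive")
    if total_orf_bp <= 0 or genome_length_bp <= 0:
        raise ValueError("coding_statistics: lengths must be positive")
    if total_orf_bp > genome_length_bp:
        warnings.warn(
            "total ORF length exceeds genome length (overlapping ORFs?)",
            stacklevel=2,
        )
    coding_percent = _round_half_up(100.0 * total_orf_bp / genome_length_bp, 2)
    mean_gene_length = int(_round_half_up(total_orf_bp / n_orfs))
    return coding_percent, mean_gene_length


def interval_span(start: int, end: int) -> int:
    """Length of a half-open 1-based coordinate interval: ``end - start``."""
    if end < start:
        raise ValueError(f"interval_span: end ({end}) < start ({start})")
    return end - start


def summarize_genome(
    genome: GenomeRecord, orf_lengths_bp: list[int]
) -> GenomeSummary:
    """Assemble the full descriptive summary for one genome."""
    total_orf_bp = int(sum(orf_lengths_bp))
    n_orfs = len(orf_lengths_bp)
    coding_percent, mean_len = coding_statistics(
        total_orf_bp, n_orfs, len(genome)
    )
    return GenomeSummary(
        genome_id=genome.genome_id,
        length_bp=len(genome),
        gc_percent=gc_content(genome.sequence),
        n_orfs=n_orfs,
        total_orf_bp=total_orf_bp,
        coding_percent=coding_percent,
        mean_gene_length_bp=mean_len,
    )
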