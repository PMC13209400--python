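"""Binomial enrichment index for COG categories in a focal gene set.

For a category with background proportion p and a focal set of n
annotated genes of which x carry the category, the enrichment index is
the number of binomial standard deviations separating the observation
from its expectation:

    EI = (x - n * p) / sqrt(n * p * (1 - p))

EI > 2 is called significant enrichment (roughly the one-sided 5% normal
tail).  Genes carrying several category letters contribute once to each
letter; genes without any COG annotation are excluded from n.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

EI_THRESHOLD = 2.0


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    x: int
    n: int
    p_bg: float
    ei: float

    @property
    def significant(self) -> bool:
        return self.ei > EI_THRESHOLD


def enrichment_index(x: int, n: int, p_bg: float) -> float:
    """Standard-deviation distance of x from its binomial expectation."""
    if n < 1:
        raise ValueError("enrichment_index: n must be >= 1")
    if not 0.0 < p_bg < 1.0:
        raise ValueError("enrichment_index: p_bg must lie strictly in (0, 1)")
    if x > n or x < 0:
        raise ValueError("enrichment_index: x must lie in [0, n]")
    return (x - n * p_bg) / math.sqrt(n * p_bg * (1.0 - p_bg))


def _category_counts(gene_cogs: Iterable[frozenset[str] | set[str]]) -> tuple[Counter, int]:
    """Per-letter gene counts and the number of COG-annotated genes."""
    counts: Counter[str] = Counter()
    n_annotated = 0
    for letters in gene_cogs:
        if letters:
            n_annotated += 1
            for letter in set(letters):
                counts[letter] += 1
    return counts, n_annotated


def category_enrichment(
    focal: Iterable[frozenset[str] | set[str]],
    background: Iterable[frozenset[str] | set[str]],
) -> list[EnrichmentResult]:
    """Enrichment index per COG category of a focal set vs a background.

    ``focal`` and ``background`` are the per-gene COG letter sets; the
    background is typically all annotated genes of the pan-genome (the
    focal set drawn from it).  One result is returned per category
    present in the background with background proportion strictly inside
    (0, 1); categories carried by every background gene are untestable
    and skipped.
    """
    bg_counts, bg_n = _category_counts(background)
    focal_counts, focal_n = _category_counts(focal)
    if bg_n == 0:
        raise ValueError("category_enrichment: background has no annotated genes")
    if focal_n == 0:
        raise ValueError("category_enrichment: focal set has no annotated genes")
    results = []
    for letter in sorted(bg_counts):
        p_bg = bg_counts[letter] / bg_n
        if not 0.0 < p_bg < 1.0:
            continue
        x = focal_counts.get(letter, 0)
        results.append(
            EnrichmentResult(
                category=letter,
                x=x,
                n=focal_n,
                p_bg=p_bg,
                ei=enrichment_index(x, focal_n, p_bg),
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "observed": [r.x for r in results],
            "focal_n": [r.n for r in results],
            "background_proportion": [r.p_bg for r in results],
            "enrichment_index": [r.ei for r in results],
            "significant": [r.significant for r in results],
        }
    )
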