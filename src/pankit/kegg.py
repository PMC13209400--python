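"""KEGG-module completeness scoring and profile clustering.

Module completeness per genome is judged by the number of unsatisfied
steps (a step is satisfied when any of its alternative KOs is
annotated): complete = no step missing, almost complete = 1-2 steps
missing, partially complete = 3 or more missing but at least one module
KO present, absent = no module KO annotated at all.  Categories map to
an ordinal score (default 0/1/2/3) whose per-genome profiles are
compared by Euclidean distance and clustered with UPGMA.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ModuleDefinition


class CompletenessCategory(IntEnum):
    """Ordinal module completeness levels."""

    ABSENT = 0
    PARTIALLY_COMPLETE = 1
    ALMOST_COMPLETE = 2
    COMPLETE = 3


#: Default numeric mapping of categories; any strictly monotone mapping
#: preserves every ordinal conclusion drawn downstream.
DEFAULT_SCORES: dict[CompletenessCategory, int] = {
    CompletenessCategory.ABSENT: 0,
    CompletenessCategory.PARTIALLY_COMPLETE: 1,
    CompletenessCategory.ALMOST_COMPLETE: 2,
    CompletenessCategory.COMPLETE: 3,
}


@dataclass(frozen=True)
class ModuleCompleteness:
    """Completeness of one module in one genome."""

    genome_id: str
    module_id: str
    n_steps: int
    n_missing: int
    category: CompletenessCategory
    score: int


def _validate_scores(scores: Mapping[CompletenessCategory, int]) -> None:
    ordered = [scores[c] for c in sorted(CompletenessCategory)]
    if any(b <= a for a, b in zip(ordered, ordered[1:])):
        raise ValueError("score mapping must be strictly increasing in completeness")


def module_completeness(
    module: ModuleDefinition,
    kos: set[str],
    scores: Mapping[CompletenessCategory, int] = DEFAULT_SCORES,
    genome_id: str = "",
) -> ModuleCompleteness:
    """Score one module against one genome's annotated KO set."""
    _validate_scores(scores)
    n_missing = sum(1 for group in module.steps if not (group & kos))
    if not (module.all_kos & kos):
        category = CompletenessCategory.ABSENT
    elif n_missing == 0:
        category = CompletenessCategory.COMPLETE
    elif n_missing <= 2:
        category = CompletenessCategory.ALMOST_COMPLETE
    else:
        category = CompletenessCategory.PARTIALLY_COMPLETE
    return ModuleCompleteness(
        genome_id=genome_id,
        module_id=module.module_id,
        n_steps=module.n_steps,
        n_missing=n_missing,
        category=category,
        score=scores[category],
    )


def completeness_matrix(
    genome_kos: Mapping[str, set[str]],
    modules: list[ModuleDefinition],
    scores: Mapping[CompletenessCategory, int] = DEFAULT_SCORES,
) -> pd.DataFrame:
    """Numeric module-by-genome completeness score matrix.

    Rows are modules and columns genomes, both sorted by id for a
    deterministic layout.
    """
    if not genome_kos or not modules:
        raise ValueError("completeness_matrix: need >= 1 genome and >= 1 module")
    genome_ids = sorted(genome_kos)
    module_ids = [m.module_id for m in modules]
    if len(set(module_ids)) != len(module_ids):
        raise ValueError("duplicate module ids")
    mods = sorted(modules, key=lambda m: m.module_id)
    data = {
        g: [module_completeness(m, genome_kos[g], scores).score for m in mods]
        for g in genome_ids
    }
    matrix = pd.DataFrame(data, index=[m.module_id for m in mods])
    matrix.index.name = "module_id"
    return matrix


def profile_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between genome score profiles (columns)."""
    if matrix.shape[1] < 2:
        raise ValueError("profile_distance: need >= 2 genomes")
    values = matrix.to_numpy(dtype=float)
    diff = values[:, :, None] - values[:, None, :]
    dist = np.sqrt((diff ** 2).sum(axis=0))
    out = pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)
    out.index.name = "id"
    return out


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """An ultrametric tree as an ordered merge list.

    Each merge joins two current clusters (named by the sorted tuple of
    their leaves) at a height equal to half the average between-cluster
    distance; heights are nondecreasing.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    def cophenetic(self) -> pd.DataFrame:
        """Cophenetic distance matrix implied by the merge heights."""
        ids = sorted(self.leaves)
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for left, right, height in self.merges:
            for a in left:
                for b in right:
                    mat.loc[a, b] = mat.loc[b, a] = 2.0 * height
        return mat

    def newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        node_height: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.leaves}
        node_text: dict[tuple[str, ...], str] = {(l,): l for l in self.leaves}
        text = ""
        for left, right, height in self.merges:
            joined = tuple(sorted(left + right))
            bl_left = height - node_height[left]
            bl_right = height - node_height[right]
            text = (
                f"({node_text[left]}:{bl_left:g},{node_text[right]}:{bl_right:g})"
            )
            node_text[joined] = text
            node_height[joined] = height
        return text + ";"


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the pair of clusters with the smallest average
    between-cluster distance is merged at half that distance; ties are
    broken by the lexicographically smallest pair of cluster labels (a
    cluster's label is its sorted leaf tuple), so the result is
    deterministic.
    """
    ids = list(dist.index)
    if len(ids) < 2:
        raise ValueError("upgma: need >= 2 leaves")
    values = dist.to_numpy(dtype=float)
    if list(dist.columns) != ids or not np.allclose(values, values.T):
        raise ValueError("upgma: distance matrix must be symmetric with matching labels")
    if np.any(np.diag(values) != 0):
        raise ValueError("upgma: nonzero diagonal")

    # distances keyed per leaf; average linkage computed from leaf pairs
    leaf_dist = {(a, b): values[i, j] for i, a in enumerate(ids) for j, b in enumerate(ids)}

    def avg(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return sum(leaf_dist[(a, b)] for a in c1 for b in c2) / (len(c1) * len(c2))

    merges = []
    active: list[tuple[str, ...]] = sorted((a,) for a in ids)
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                c1, c2 = sorted((active[i], active[j]))
                d = avg(c1, c2)
                key = (d, c1, c2)
                if best is None or key < best:
                    best = key
        d, c1, c2 = best
        merges.append((c1, c2, d / 2.0))
        active = sorted(
            [c for c in active if c not in (c1, c2)] + [tuple(sorted(c1 + c2))]
        )
    return Dendrogram(leaves=tuple(ids), merges=tuple(merges))
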