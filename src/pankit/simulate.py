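"""Synthetic comparative-genomics datasets with known ground truth.

The generator emulates the structure of a 16-genome bacterial dataset
(2 hydrothermal-vent and 14 non-vent genomes): gene families with
core/accessory/unique architecture, planted environment-associated
presence patterns, COG category annotation, KO content for defined
metabolic modules, and nucleotide/protein sequences evolved from random
ancestors at controlled divergence.  Every generator is a pure function
of its spec and seed, so the planted truth serves as an exact oracle for
the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    AnnotationRow,
    AnnotationTable,
    Environment,
    GenomeRecord,
    MetadataRow,
    MetadataTable,
    ModuleDefinition,
    ProteinRecord,
)

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Background COG letter frequencies used for annotation draws; a rough
#: bacterial genome profile (heavier metabolic/unknown categories).
DEFAULT_COG_WEIGHTS: dict[str, float] = {
    "C": 0.08, "E": 0.09, "G": 0.05, "H": 0.05, "I": 0.03, "J": 0.07,
    "K": 0.06, "L": 0.06, "M": 0.07, "N": 0.03, "O": 0.04, "P": 0.06,
    "Q": 0.02, "S": 0.15, "T": 0.07, "U": 0.03, "V": 0.04,
}

#: Letters over-represented in the planted vent-associated clusters
#: (amino-acid and coenzyme metabolism, mirroring a vent-adaptation
#: signature) and their multiplier over the background weight.
DEFAULT_FOCAL_BIAS: dict[str, float] = {"E": 3.0, "H": 3.0}


@dataclass(frozen=True)
class SyntheticPangenomeSpec:
    """Study design of a synthetic pan-genome.

    Defaults mirror the reference 16-genome design: 2 HTV vs 14 non-HTV
    genomes, ~800 core families, a U-shaped accessory occupancy spectrum
    (Beta(0.3, 0.3) occurrence probabilities, yielding an open
    pan-genome), per-genome unique families, and 57 + 82 planted
    environment-specific patterns.
    """

    n_genomes: int = 16
    n_htv: int = 2
    n_core: int = 800
    n_accessory: int = 2800
    accessory_beta: tuple[float, float] = (0.3, 0.3)
    unique_rate: float = 250.0
    n_planted_htv: int = 57
    n_planted_nonhtv: int = 82
    planted_leak: int = 0  # planted HTV patterns may appear in this many non-HTV genomes
    cog_weights: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_COG_WEIGHTS.items()))
    focal_bias: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_FOCAL_BIAS.items()))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_htv < self.n_genomes:
            raise ValueError("need 0 < n_htv < n_genomes")
        if min(self.n_core, self.n_accessory, self.n_planted_htv,
               self.n_planted_nonhtv) < 0 or self.unique_rate < 0:
            raise ValueError("counts and rates must be non-negative")
        a, b = self.accessory_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class SequenceEvolutionSpec:
    """Mutation model for evolving a descendant from an ancestor."""

    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    alphabet: str = "nucleotide"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ValueError("rates must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated pan-genome."""

    core: set[str]
    accessory: set[str]
    unique: dict[str, set[str]]
    planted_htv: set[str]
    planted_nonhtv: set[str]

    @property
    def n_clusters(self) -> int:
        return (
            len(self.core) + len(self.accessory)
            + sum(len(v) for v in self.unique.values())
            + len(self.planted_htv) + len(self.planted_nonhtv)
        )


def _significant_pattern(present_htv: int, n_htv: int, present_non: int, n_non: int) -> bool:
    """Would this presence pattern pass the raw-p Fisher screen at 0.05?

    Used to keep randomly drawn background families from colliding with
    the planted association truth (checked with the same exact test the
    analysis uses).
    """
    from .association import ContingencyTable2x2, fisher_exact_2x2, is_below_alpha

    if present_htv + present_non in (0, n_htv + n_non):
        return False  # core or empty: never tested
    table = ContingencyTable2x2(
        present_htv, n_htv - present_htv, present_non, n_non - present_non
    )
    return is_below_alpha(fisher_exact_2x2(table), 0.05)


def simulate_pangenome(
    spec: SyntheticPangenomeSpec,
) -> tuple[pd.DataFrame, AnnotationTable, MetadataTable, PlantedTruth]:
    """Draw a presence/absence pan-genome with planted structure.

    Core families are present everywhere; accessory families draw a
    per-family occurrence probability from the Beta spectrum and then
    per-genome Bernoulli presence; unique families attach to single
    genomes (Poisson counts per genome); planted environment patterns
    are present in every genome of their group and in at most
    ``planted_leak`` genomes of the other.  Background accessory draws
    whose pattern would itself pass the association screen are redrawn,
    so the planted sets are exactly the significant truth.

    Annotation assigns each present gene a COG letter set (biased for
    planted HTV clusters) and is returned protein-level, one
    representative gene per present cluster/genome cell.
    """
    rng = np.random.default_rng(spec.seed)
    genome_ids = [f"SG{i + 1:02d}" for i in range(spec.n_genomes)]
    htv = genome_ids[: spec.n_htv]
    nonhtv = genome_ids[spec.n_htv:]
    meta = MetadataTable(
        [MetadataRow(g, Environment.HTV, f"vent strain {g}") for g in htv]
        + [MetadataRow(g, Environment.NONHTV, f"reference strain {g}") for g in nonhtv]
    )

    rows: dict[str, np.ndarray] = {}
    truth = PlantedTruth(set(), set(), {g: set() for g in genome_ids}, set(), set())

    def add(cluster_id: str, presence: np.ndarray) -> None:
        rows[cluster_id] = presence

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:05d}"

    for _ in range(spec.n_core):
        cid = next_id()
        add(cid, np.ones(spec.n_genomes, dtype=bool))
        truth.core.add(cid)

    a, b = spec.accessory_beta
    n_drawn = 0
    while n_drawn < spec.n_accessory:
        prob = rng.beta(a, b)
        presence = rng.random(spec.n_genomes) < prob
        count = presence.sum()
        if count < 2 or count == spec.n_genomes:
            continue  # must be accessory by definition
        if _significant_pattern(
            int(presence[: spec.n_htv].sum()), spec.n_htv,
            int(presence[spec.n_htv:].sum()), spec.n_genomes - spec.n_htv,
        ):
            continue  # keep background clear of the planted association truth
        cid = next_id()
        add(cid, presence)
        truth.accessory.add(cid)
        n_drawn += 1

    for gi, genome in enumerate(genome_ids):
        for _ in range(rng.poisson(spec.unique_rate)):
            presence = np.zeros(spec.n_genomes, dtype=bool)
            presence[gi] = True
            cid = next_id()
            add(cid, presence)
            truth.unique[genome].add(cid)

    n_non = spec.n_genomes - spec.n_htv
    for _ in range(spec.n_planted_htv):
        presence = np.zeros(spec.n_genomes, dtype=bool)
        presence[: spec.n_htv] = True
        if spec.planted_leak:
            leak = rng.choice(n_non, size=spec.planted_leak, replace=False)
            presence[spec.n_htv + leak] = True
        cid = next_id()
        add(cid, presence)
        truth.planted_htv.add(cid)
    for _ in range(spec.n_planted_nonhtv):
        presence = np.ones(spec.n_genomes, dtype=bool)
        presence[: spec.n_htv] = False
        if spec.planted_leak:
            drop = rng.choice(n_non, size=spec.planted_leak, replace=False)
            presence[spec.n_htv + drop] = False
        cid = next_id()
        add(cid, presence)
        truth.planted_nonhtv.add(cid)

    matrix = pd.DataFrame.from_dict(
        dict(sorted(rows.items())), orient="index", columns=genome_ids
    )
    matrix.index.name = "cluster_id"

    # --- annotation: one representative gene per present cell -------------
    letters_bg = [l for l, _ in spec.cog_weights]
    w_bg = np.array([w for _, w in spec.cog_weights])
    w_bg = w_bg / w_bg.sum()
    bias = dict(spec.focal_bias)
    w_focal = np.array(
        [w * bias.get(l, 1.0) for l, w in zip(letters_bg, w_bg)]
    )
    w_focal = w_focal / w_focal.sum()
    ann_rows = []
    for cid, presence in sorted(rows.items()):
        focal = cid in truth.planted_htv
        weights = w_focal if focal else w_bg
        letters = frozenset(rng.choice(letters_bg, p=weights, size=1))
        if rng.random() < 0.1:  # a minority of genes carry two letters
            letters = letters | {rng.choice(letters_bg, p=weights)}
        for gi in np.flatnonzero(presence):
            genome = genome_ids[gi]
            ann_rows.append(
                AnnotationRow(f"{genome}|{cid}", genome, letters, frozenset())
            )
    annotation = AnnotationTable(ann_rows)
    return matrix, annotation, meta, truth


# ---------------------------------------------------------------------------
# module KO plans
# ---------------------------------------------------------------------------

def default_module_plan(
    n_modules_shared: int = 16,
    n_modules_vent: int = 3,
    n_steps: int = 4,
) -> list[ModuleDefinition]:
    """Synthetic module definitions: shared housekeeping + vent modules.

    The vent modules are desk-scale analogues of the cofactor pathways
    (heme, glycine cleavage, lipoate) that distinguish vent strains.
    """
    modules = []
    ko = iter(range(10000, 20000))
    for m in range(n_modules_shared + n_modules_vent):
        steps = tuple(
            frozenset({f"K{next(ko):05d}", f"K{next(ko):05d}"})
            for _ in range(n_steps)
        )
        tag = "V" if m >= n_modules_shared else "S"
        modules.append(ModuleDefinition(f"M{tag}{m + 1:03d}", steps))
    return modules


def assign_module_kos(
    modules: list[ModuleDefinition],
    metadata: MetadataTable,
    vent_prefix: str = "MV",
    seed: int = 0,
) -> dict[str, set[str]]:
    """Per-genome KO sets realising a vent/non-vent module plan.

    Modules whose id starts with ``vent_prefix`` are complete in HTV
    genomes and absent elsewhere; every other (shared) module is
    complete everywhere, except that the j-th non-HTV genome misses one
    step of the j-th shared module.  The perturbations keep every
    non-vent profile distinct (when there are at least as many shared
    modules as non-vent genomes) while leaving the two vent genomes as
    the unique closest pair, so the profile dendrogram's first merge is
    the vent pair.  The seed only varies which alternative KO satisfies
    each step.
    """
    rng = np.random.default_rng(seed)
    shared = [m for m in modules if not m.module_id.startswith(vent_prefix)]
    skip_plan = {  # genome -> (module_id, step index withheld)
        genome: (shared[j % len(shared)].module_id, (j // len(shared)) % shared[0].n_steps)
        for j, genome in enumerate(metadata.group(Environment.NONHTV))
        if shared
    }
    out: dict[str, set[str]] = {g: set() for g in metadata.genome_ids}
    for module in modules:
        vent_only = module.module_id.startswith(vent_prefix)
        for row in metadata:
            if vent_only and row.environment != Environment.HTV:
                continue
            skip = skip_plan.get(row.genome_id)
            for s, group in enumerate(module.steps):
                if skip == (module.module_id, s):
                    continue
                out[row.genome_id].add(
                    sorted(group)[int(rng.integers(len(group)))]
                )
    return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def random_sequence(length: int, alphabet: str = "nucleotide", seed: int = 0) -> str:
    """Uniform random sequence over the chosen alphabet."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pool = NUCLEOTIDES if alphabet == "nucleotide" else AMINO_ACIDS
    return "".join(rng.choice(pool, size=length))


def evolve_sequence(ancestor: str, spec: SequenceEvolutionSpec) -> str:
    """Evolve a descendant: per-site substitutions, then indels.

    Each site is substituted with probability ``substitution_rate`` to a
    uniformly chosen different symbol.  Indels (expected
    ``indel_rate * length`` events, single-symbol, insertion or deletion
    with equal probability) are applied after substitution.
    """
    if not ancestor:
        raise ValueError("evolve_sequence: empty ancestor")
    rng = np.random.default_rng(spec.seed)
    pool = NUCLEOTIDES if spec.alphabet == "nucleotide" else AMINO_ACIDS
    seq = np.array(list(ancestor))
    hit = rng.random(seq.size) < spec.substitution_rate
    for i in np.flatnonzero(hit):
        choices = pool[pool != seq[i]]
        seq[i] = choices[int(rng.integers(choices.size))]
    out = list(seq)
    if spec.indel_rate > 0:
        n_events = rng.poisson(spec.indel_rate * len(out))
        for _ in range(n_events):
            pos = int(rng.integers(len(out) + 1))
            if rng.random() < 0.5 and len(out) > 1:
                del out[min(pos, len(out) - 1)]
            else:
                out.insert(pos, str(pool[int(rng.integers(pool.size))]))
    return "".join(out)


def simulate_genome_pair(
    length: int = 100_000, substitution_rate: float = 0.05, seed: int = 0
) -> tuple[GenomeRecord, GenomeRecord]:
    """An ancestor genome and its descendant at a known divergence.

    With no indels the expected per-site identity of the pair is exactly
    1 - substitution_rate, making the pair an analytic oracle for ANI.
    """
    ancestor = random_sequence(length, "nucleotide", seed)
    child = evolve_sequence(
        ancestor,
        SequenceEvolutionSpec(
            substitution_rate=substitution_rate, indel_rate=0.0,
            alphabet="nucleotide", seed=seed + 1,
        ),
    )
    return (
        GenomeRecord("ancestor", ancestor),
        GenomeRecord("descendant", child),
    )


def simulate_proteomes(
    n_genomes: int,
    n_families: int,
    divergence: float,
    seed: int = 0,
    length_range: tuple[int, int] = (80, 400),
) -> tuple[dict[str, list[ProteinRecord]], dict[str, str]]:
    """Per-genome proteomes evolved from per-family ancestral proteins.

    Every family draws a random ancestor protein (length uniform in
    ``length_range``); every genome carries one descendant evolved at
    amino-acid divergence ``divergence``.  Returns the proteomes and the
    protein-to-family truth labels used as the clustering oracle.
    """
    if n_families < 1 or n_genomes < 1:
        raise ValueError("need >= 1 family and >= 1 genome")
    rng = np.random.default_rng(seed)
    genome_ids = [f"SG{i + 1:02d}" for i in range(n_genomes)]
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in genome_ids}
    labels: dict[str, str] = {}
    for f in range(n_families):
        family = f"FAM{f + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = "".join(rng.choice(AMINO_ACIDS, size=length))
        for genome in genome_ids:
            child = evolve_sequence(
                ancestor,
                SequenceEvolutionSpec(
                    substitution_rate=divergence, indel_rate=0.0,
                    alphabet="protein", seed=int(rng.integers(2**31 - 1)),
                ),
            )
            pid = f"{genome}|{family}"
            proteomes[genome].append(ProteinRecord(pid, genome, child))
            labels[pid] = family
    return proteomes, labels
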