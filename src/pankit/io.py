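"""Reading, writing and validation of the external file formats.

Everything the pipeline consumes or emits passes through this module:
FASTA genomes and proteomes, tab-separated annotation / metadata / module
tables, presence-absence matrices, and Newick dendrograms.  All readers
fail fast on malformed input rather than silently masking it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pankit")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: The 26 single-letter COG functional category codes.
COG_LETTERS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
KO_PATTERN = re.compile(r"^K\d{5}$")

FASTA_LINE_WIDTH = 70


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


class Environment(str, Enum):
    """Isolation-source label contrasted by the association test."""

    HTV = "HTV"
    NONHTV = "nonHTV"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide genome with its isolation-source label."""

    genome_id: str
    sequence: str
    environment: Environment = Environment.UNKNOWN
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.genome_id!r}: illegal nucleotide symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence attached to its source genome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r}: illegal residue symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRow:
    protein_id: str
    genome_id: str
    cog_letters: frozenset[str]
    kos: frozenset[str]


@dataclass
class AnnotationTable:
    """Per-protein functional annotation: COG category letters and KOs."""

    rows: list[AnnotationRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            bad_cog = row.cog_letters - COG_LETTERS
            if bad_cog:
                raise FormatError(
                    f"protein {row.protein_id!r}: invalid COG letters {sorted(bad_cog)}"
                )
            for ko in row.kos:
                if not KO_PATTERN.match(ko):
                    raise FormatError(
                        f"protein {row.protein_id!r}: malformed KO id {ko!r}"
                    )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def by_genome_kos(self) -> dict[str, set[str]]:
        """Union of KO identifiers annotated per genome."""
        out: dict[str, set[str]] = {}
        for row in self.rows:
            out.setdefault(row.genome_id, set()).update(row.kos)
        return out


@dataclass(frozen=True)
class MetadataRow:
    genome_id: str
    environment: Environment
    name: str = ""


@dataclass
class MetadataTable:
    """Genome-level metadata: environment grouping and display names."""

    rows: list[MetadataRow]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.genome_id in seen:
                raise FormatError(f"duplicate genome id {row.genome_id!r} in metadata")
            seen.add(row.genome_id)
            if row.environment not in (Environment.HTV, Environment.NONHTV):
                raise FormatError(
                    f"genome {row.genome_id!r}: environment must be HTV or nonHTV"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.rows]

    def environment_of(self, genome_id: str) -> Environment:
        for row in self.rows:
            if row.genome_id == genome_id:
                return row.environment
        raise KeyError(genome_id)

    def group(self, environment: Environment) -> list[str]:
        return [r.genome_id for r in self.rows if r.environment == environment]


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module as an ordered list of KO alternative groups.

    A step is satisfied when any KO in its group is annotated in the
    genome; module completeness is judged by the number of unsatisfied
    steps (the missing-KO count).
    """

    module_id: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise FormatError(f"module {self.module_id!r}: no steps")
        for group in self.steps:
            if not group:
                raise FormatError(f"module {self.module_id!r}: empty KO group")
            for ko in group:
                if not KO_PATTERN.match(ko):
                    raise FormatError(
                        f"module {self.module_id!r}: malformed KO id {ko!r}"
                    )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def all_kos(self) -> frozenset[str]:
        out: set[str] = set()
        for group in self.steps:
            out |= group
        return frozenset(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    alphabet: str,
    genome_id: str | None = None,
    metadata: MetadataTable | None = None,
) -> list[GenomeRecord] | list[ProteinRecord]:
    """Read a FASTA file into typed records.

    Parameters
    ----------
    path:
        FASTA file.  Sequences are upper-cased on read; for nucleotides,
        ``U`` is folded to ``T``.  Any symbol outside the declared
        alphabet is an error naming the offending record.
    alphabet:
        ``"nucleotide"`` (one GenomeRecord per entry) or ``"protein"``
        (one ProteinRecord per entry).
    genome_id:
        For protein FASTAs: the genome the proteins belong to.  Defaults
        to the file stem.
    metadata:
        Optional; when given, genome environments are looked up from it.
    """
    path = Path(path)
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise FormatError(f"{path}: empty or headerless FASTA file")
    ids = [r.id for r in raw]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record ids {dupes}")

    records: list = []
    for rec in raw:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
            env = Environment.UNKNOWN
            if metadata is not None:
                try:
                    env = metadata.environment_of(rec.id)
                except KeyError:
                    pass
            records.append(
                GenomeRecord(rec.id, seq, environment=env, label=rec.description)
            )
        else:
            records.append(
                ProteinRecord(rec.id, genome_id or path.stem, seq)
            )
    return records


def write_fasta(records: Iterable[GenomeRecord | ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 70 columns."""
    path = Path(path)
    seqs = []
    for rec in records:
        rid = rec.genome_id if isinstance(rec, GenomeRecord) else rec.protein_id
        seqs.append(SeqRecord(Seq(rec.sequence), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# TSV tables (tab-separated, UTF-8, '#' comment lines skipped)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a protein annotation TSV (protein_id, genome_id, cog, kos).

    ``cog`` is a string of category letters ("TP" means {T, P}); ``kos``
    is a semicolon-joined list of KO identifiers.  Empty cells mean no
    annotation of that kind.
    """
    df = _read_tsv(path, ["protein_id", "genome_id", "cog", "kos"])
    rows = []
    for rec in df.itertuples(index=False):
        kos = frozenset(k for k in rec.kos.split(";") if k)
        rows.append(
            AnnotationRow(rec.protein_id, rec.genome_id, frozenset(rec.cog), kos)
        )
    return AnnotationTable(rows)


def read_metadata_table(path: str | Path) -> MetadataTable:
    """Read genome metadata TSV (genome_id, environment, name)."""
    df = _read_tsv(path, ["genome_id", "environment", "name"])
    rows = []
    for rec in df.itertuples(index=False):
        try:
            env = Environment(rec.environment)
        except ValueError:
            raise FormatError(
                f"{path}: genome {rec.genome_id!r} has environment "
                f"{rec.environment!r}; expected HTV or nonHTV"
            ) from None
        rows.append(MetadataRow(rec.genome_id, env, rec.name))
    return MetadataTable(rows)


def read_module_table(path: str | Path) -> list[ModuleDefinition]:
    """Read module definitions TSV (module_id, step_index, kos).

    ``kos`` is a comma-joined group of alternative KOs satisfying the
    step.  Steps are ordered by ``step_index`` within each module; input
    row order of modules is preserved.
    """
    df = _read_tsv(path, ["module_id", "step_index", "kos"])
    order: list[str] = []
    steps: dict[str, list[tuple[int, frozenset[str]]]] = {}
    for rec in df.itertuples(index=False):
        if rec.module_id not in steps:
            steps[rec.module_id] = []
            order.append(rec.module_id)
        group = frozenset(k for k in rec.kos.split(",") if k)
        steps[rec.module_id].append((int(rec.step_index), group))
    modules = []
    for mid in order:
        ordered = tuple(g for _, g in sorted(steps[mid], key=lambda t: t[0]))
        modules.append(ModuleDefinition(mid, ordered))
    return modules


def read_tables(
    annotation_path: str | Path,
    metadata_path: str | Path,
    module_path: str | Path,
) -> tuple[AnnotationTable, MetadataTable, list[ModuleDefinition]]:
    """Read the three companion tables of a comparative-genomics run."""
    ann = read_annotation_table(annotation_path)
    meta = read_metadata_table(metadata_path)
    mods = read_module_table(module_path)
    known = set(meta.genome_ids)
    for row in ann:
        if row.genome_id not in known:
            raise FormatError(
                f"annotation references genome {row.genome_id!r} absent from metadata"
            )
    return ann, meta, mods


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in table],
            "genome_id": [r.genome_id for r in table],
            "cog": ["".join(sorted(r.cog_letters)) for r in table],
            "kos": [";".join(sorted(r.kos)) for r in table],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_metadata_table(table: MetadataTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in table],
            "environment": [r.environment.value for r in table],
            "name": [r.name for r in table],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_module_table(modules: Iterable[ModuleDefinition], path: str | Path) -> None:
    recs = []
    for mod in modules:
        for i, group in enumerate(mod.steps):
            recs.append((mod.module_id, i, ",".join(sorted(group))))
    pd.DataFrame(recs, columns=["module_id", "step_index", "kos"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Matrices and trees
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a cluster-by-genome (or module-by-genome) matrix as TSV."""
    out = matrix.copy()
    if out.dtypes.map(lambda d: d == bool).all():
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="id")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Read a presence/absence matrix TSV back into a boolean DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df.astype(bool)


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")
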