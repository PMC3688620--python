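"""Gene-model-aware protein sequence databases.

A database is a flat collection of protein records, each tied to one
transcript and one gene model.  Several transcripts of a gene may encode
the same protein sequence (UTR-only differences), and distinct gene models
may encode identical products (duplicated loci such as histones).  The
identical-sequence partition and the gene index drive downstream peptide
evidence classification.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DECOY_PREFIX = "DECOY_"

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class DatabaseError(ValueError):
    """Malformed or inconsistent sequence database."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its transcript/gene-model provenance."""

    protein_id: str
    transcript_id: str
    gene_id: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"empty sequence for record {self.protein_id!r}")
        if not self.sequence.isupper():
            raise DatabaseError(f"sequence not uppercase for {self.protein_id!r}")


class SequenceDB:
    """Immutable collection of :class:`ProteinRecord` with derived indices.

    ``seq_index`` partitions records into identical-sequence classes
    (exact string equality); ``gene_index`` maps gene ids to their records.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        seen: set[str] = set()
        tr2gene: dict[str, str] = {}
        for rec in self.records:
            if rec.protein_id in seen:
                raise DatabaseError(f"duplicate protein_id {rec.protein_id!r}")
            seen.add(rec.protein_id)
            prior = tr2gene.setdefault(rec.transcript_id, rec.gene_id)
            if prior != rec.gene_id:
                raise DatabaseError(
                    f"transcript {rec.transcript_id!r} mapped to two genes "
                    f"({prior!r}, {rec.gene_id!r})"
                )
        self.seq_index: dict[str, list[ProteinRecord]] = {}
        self.gene_index: dict[str, list[ProteinRecord]] = {}
        for rec in self.records:
            self.seq_index.setdefault(rec.sequence, []).append(rec)
            self.gene_index.setdefault(rec.gene_id, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def targets(self) -> list[ProteinRecord]:
        return [r for r in self.records if not r.is_decoy]

    @property
    def decoys(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.is_decoy]

    def target_db(self) -> "SequenceDB":
        return SequenceDB(self.targets)

    def decoy_db(self) -> "SequenceDB":
        return SequenceDB(self.decoys)

    def gene_sequences(self, gene_id: str) -> set[str]:
        """Distinct protein sequences encoded by one gene model."""
        return {r.sequence for r in self.gene_index[gene_id]}


def _parse_keyvalue_header(header: str) -> tuple[str, str, str]:
    tokens = header.split()
    protein_id = tokens[0]
    kv = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, val = tok.partition("=")
            kv[key] = val
    if "gene" not in kv or "transcript" not in kv:
        raise DatabaseError(
            f"header for {protein_id!r} lacks gene=/transcript= tokens"
        )
    return protein_id, kv["transcript"], kv["gene"]


HEADER_DIALECTS: dict[str, Callable[[str], tuple[str, str, str]]] = {
    "keyvalue": _parse_keyvalue_header,
}


def read_fasta_db(path: str | Path, header_dialect: str = "keyvalue") -> SequenceDB:
    """Read a FASTA database whose headers carry gene/transcript metadata.

    The default dialect expects ``>PROTID gene=G transcript=T`` headers;
    a leading ``DECOY_`` on the protein id marks a decoy record.
    """
    try:
        parse_header = HEADER_DIALECTS[header_dialect]
    except KeyError:
        raise DatabaseError(f"unknown header dialect {header_dialect!r}") from None
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        try:
            protein_id, transcript_id, gene_id = parse_header(seq_rec.description)
        except DatabaseError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise DatabaseError(f"malformed header {seq_rec.description!r}") from exc
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                transcript_id=transcript_id,
                gene_id=gene_id,
                sequence=str(seq_rec.seq).upper(),
                is_decoy=protein_id.startswith(DECOY_PREFIX),
            )
        )
    return SequenceDB(records)


def write_fasta_db(db: SequenceDB, path: str | Path) -> None:
    """Write targets then decoys with ``>id gene=G transcript=T`` headers."""
    seq_records = []
    for rec in db.targets + db.decoys:
        seq_records.append(
            SeqRecord(
                Seq(rec.sequence),
                id=rec.protein_id,
                description=f"gene={rec.gene_id} transcript={rec.transcript_id}",
            )
        )
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def build_decoy_db(
    db: SequenceDB, method: str = "reverse", seed: int | None = None
) -> SequenceDB:
    """Build one decoy record per target record.

    ``reverse`` (default) reverses each sequence; ``shuffle`` permutes it
    under ``seed``.  Ids (protein, transcript, gene) are prefixed
    ``DECOY_`` so decoy inference mirrors the target structure.
    """
    if db.decoys:
        raise DatabaseError("input database already contains decoy records")
    if method == "reverse":
        transform = lambda s, _rng: s[::-1]  # noqa: E731
    elif method == "shuffle":
        transform = lambda s, rng: "".join(rng.sample(s, len(s)))  # noqa: E731
    else:
        raise DatabaseError(f"unknown decoy method {method!r}")
    rng = random.Random(seed)
    decoys = [
        ProteinRecord(
            protein_id=DECOY_PREFIX + rec.protein_id,
            transcript_id=DECOY_PREFIX + rec.transcript_id,
            gene_id=DECOY_PREFIX + rec.gene_id,
            sequence=transform(rec.sequence, rng),
            is_decoy=True,
        )
        for rec in db.records
    ]
    return SequenceDB(decoys)


def concat_dbs(*dbs: SequenceDB) -> SequenceDB:
    return SequenceDB([r for db in dbs for r in db.records])


@dataclass
class SequenceGroup:
    """One identical-sequence class and the loci encoding it."""

    sequence: str
    protein_ids: set[str] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)


def sequence_groups(db: SequenceDB) -> list[SequenceGroup]:
    """Partition records into identical-sequence classes.

    Each class reports the distinct gene models and transcripts encoding
    that exact sequence (duplicated loci collapse into one class).
    """
    groups = []
    for seq, recs in db.seq_index.items():
        groups.append(
            SequenceGroup(
                sequence=seq,
                protein_ids={r.protein_id for r in recs},
                transcript_ids={r.transcript_id for r in recs},
                gene_ids={r.gene_id for r in recs},
            )
        )
    return groups
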