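"""Deterministic peptide evidence classification.

Each identified peptide is placed in exactly one of six classes by how
unambiguously it pins down protein sequences, transcripts and gene models:

* ``1a`` — one protein sequence, one gene, one transcript
* ``1b`` — one protein sequence, one gene, several transcripts
* ``2a`` — several sequences, one gene, a *subset* of its isoforms
* ``2b`` — several sequences, one gene, *all* of its isoforms
* ``3a`` — one protein sequence encoded by several gene models
* ``3b`` — several sequences from several gene models

Classes 1a/1b/3a are "unequivocal" (they identify a unique sequence);
2a/2b imply a unique gene model; 3b has the least information content.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .db import SequenceDB

EVIDENCE_CLASSES = ("1a", "1b", "2a", "2b", "3a", "3b")

#: classes that identify a unique protein sequence
UNEQUIVOCAL_CLASSES = frozenset({"1a", "1b", "3a"})

#: information-content order, most informative first
CLASS_PRIORITY = {"1a": 0, "1b": 1, "3a": 2, "2a": 3, "2b": 4, "3b": 5}


class NotIdentifiedError(KeyError):
    """Peptide not contained in any database record."""


@dataclass(frozen=True)
class PeptideMapping:
    """Containment sets of one peptide in a target database."""

    peptide: str
    protein_ids: frozenset[str]
    distinct_sequences: frozenset[str]
    transcript_ids: frozenset[str]
    gene_ids: frozenset[str]


def _normalize(seq: str, il_equivalent: bool) -> str:
    return seq.replace("I", "L") if il_equivalent else seq


def map_peptide(
    peptide: str, db: SequenceDB, il_equivalent: bool = False
) -> PeptideMapping:
    """Find every record containing ``peptide`` as an exact substring.

    With ``il_equivalent`` isoleucine and leucine are treated as one
    character (MS cannot distinguish them); default is strict identity.
    """
    if not peptide:
        raise ValueError("empty peptide")
    needle = _normalize(peptide, il_equivalent)
    proteins, seqs, transcripts, genes = set(), set(), set(), set()
    for rec in db.records:
        if rec.is_decoy:
            continue
        if needle in _normalize(rec.sequence, il_equivalent):
            proteins.add(rec.protein_id)
            seqs.add(_normalize(rec.sequence, il_equivalent))
            transcripts.add(rec.transcript_id)
            genes.add(rec.gene_id)
    if not proteins:
        raise NotIdentifiedError(peptide)
    return PeptideMapping(
        peptide=peptide,
        protein_ids=frozenset(proteins),
        distinct_sequences=frozenset(seqs),
        transcript_ids=frozenset(transcripts),
        gene_ids=frozenset(genes),
    )


def classify(
    mapping: PeptideMapping, db: SequenceDB, il_equivalent: bool = False
) -> str:
    """Assign the evidence class of a mapped peptide (total decision tree)."""
    n_seq = len(mapping.distinct_sequences)
    n_gene = len(mapping.gene_ids)
    if n_seq == 1:
        if n_gene > 1:
            return "3a"
        # transcripts of this gene encoding exactly this sequence
        (seq,) = mapping.distinct_sequences
        (gene,) = mapping.gene_ids
        n_tr = sum(
            1
            for r in db.gene_index[gene]
            if not r.is_decoy and _normalize(r.sequence, il_equivalent) == seq
        )
        return "1a" if n_tr == 1 else "1b"
    if n_gene == 1:
        (gene,) = mapping.gene_ids
        gene_seqs = {
            _normalize(r.sequence, il_equivalent)
            for r in db.gene_index[gene]
            if not r.is_decoy
        }
        return "2b" if mapping.distinct_sequences == gene_seqs else "2a"
    return "3b"


def classify_psms(
    psms: pd.DataFrame, db: SequenceDB, il_equivalent: bool = False
) -> pd.DataFrame:
    """Annotate a PSM table with evidence class and containment sets.

    Target peptides are mapped against target records, decoy peptides
    against decoy records (the classification procedure is identical).
    PSMs whose peptide is not contained in the respective database are
    dropped.  Containment-set columns are ``;``-joined sorted ids.
    """
    target_db = db.target_db()
    decoy_records = db.decoys
    decoy_db = (
        SequenceDB([replace(r, is_decoy=False) for r in decoy_records])
        if decoy_records
        else None
    )

    cache: dict[tuple[str, bool], tuple | None] = {}

    def lookup(peptide: str, is_decoy: bool):
        key = (peptide, is_decoy)
        if key not in cache:
            sub_db = decoy_db if is_decoy else target_db
            if sub_db is None:
                cache[key] = None
            else:
                try:
                    m = map_peptide(peptide, sub_db, il_equivalent)
                except NotIdentifiedError:
                    cache[key] = None
                else:
                    cls = classify(m, sub_db, il_equivalent)
                    cache[key] = (
                        cls,
                        ";".join(sorted(m.protein_ids)),
                        ";".join(sorted(m.transcript_ids)),
                        ";".join(sorted(m.gene_ids)),
                        len(m.distinct_sequences),
                    )
        return cache[key]

    rows = []
    for rec in psms.itertuples(index=False):
        hit = lookup(rec.peptide, bool(rec.is_decoy))
        if hit is None:
            continue
        cls, prot, tr, gene, n_seq = hit
        rows.append(
            {**rec._asdict(), "evidence_class": cls, "protein_ids": prot,
             "transcript_ids": tr, "gene_ids": gene, "n_sequences": n_seq}
        )
    return pd.DataFrame(rows)


def class_census(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-class tallies of spectra and distinct peptides.

    Returns one row per evidence class (all six, zero-filled) with columns
    ``n_spectra`` and ``n_peptides``; distinct-protein counting is the
    inference module's job.
    """
    out = pd.DataFrame(
        0, index=list(EVIDENCE_CLASSES), columns=["n_spectra", "n_peptides"]
    )
    out.index.name = "evidence_class"
    if len(classified):
        grouped = classified.groupby("evidence_class")
        out.loc[grouped.size().index, "n_spectra"] = grouped.size()
        npep = grouped["peptide"].nunique()
        out.loc[npep.index, "n_peptides"] = npep
    return out.reset_index()
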