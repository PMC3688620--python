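import numpy as np
import pandas as pd
import pytest

from hemoshotgun.db import ProteinRecord, SequenceDB

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def make_db(*triples) -> SequenceDB:
    """Build a SequenceDB from (protein_id, transcript_id, gene_id, seq)."""
    return SequenceDB(
        [ProteinRecord(p, t, g, s) for p, t, g, s in triples]
    )


def random_db(rng: np.random.Generator, n_records: int, seq_len: int = 40):
    """Random database with sequence sharing across transcripts and genes.

    Deliberately injects identical sequences within and across genes and
    partially shared sequences so that all six evidence classes occur.
    """
    records = []
    pool: list[str] = []
    for i in range(n_records):
        gene = f"g{rng.integers(max(1, n_records // 2)):03d}"
        mode = rng.random()
        if pool and mode < 0.2:
            seq = pool[int(rng.integers(len(pool)))]  # exact duplicate
        elif pool and mode < 0.4:
            donor = pool[int(rng.integers(len(pool)))]
            cut = int(rng.integers(5, max(6, len(donor) - 5)))
            seq = donor[:cut] + random_protein(rng, seq_len - cut)
        else:
            seq = random_protein(rng, seq_len)
        pool.append(seq)
        records.append(ProteinRecord(f"p{i:03d}", f"t{i:03d}", gene, seq))
    return SequenceDB(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_db():
    # gA: two transcripts, identical product; gB: two isoforms sharing a
    # region; gC/gD: duplicated locus; gE: single transcript
    shared = "WWNDFGHTTYE"
    return make_db(
        ("pA1", "tA1", "gA", "MKAAAGGGWPK"),
        ("pA2", "tA2", "gA", "MKAAAGGGWPK"),
        ("pB1", "tB1", "gB", shared + "AAACCC"),
        ("pB2", "tB2", "gB", shared + "DDDEEE"),
        ("pC1", "tC1", "gC", "MHHHHLLLNQSTV"),
        ("pD1", "tD1", "gD", "MHHHHLLLNQSTV"),
        ("pE1", "tE1", "gE", "MTTTVVVYYYW"),
    )


def psm_frame(rows):
    """rows: (spectrum_id, peptide, score, is_decoy, sample)"""
    return pd.DataFrame(
        rows, columns=["spectrum_id", "peptide", "score", "is_decoy", "sample"]
    )
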