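"""Synthetic gene-model databases and two-condition PSM tables.

Databases are built from exon-like blocks: each block is a fixed-length
stretch of non-cleaving residues terminated by lysine, so its fully
tryptic digest is the block itself.  Reusing blocks across isoforms and
loci gives exact control over peptide sharing, and therefore over which
evidence class every theoretical peptide falls into:

========================  =============================  ================
construct                 structure                      classes realized
========================  =============================  ================
single                    one transcript, unique blocks  1a
identical_isoforms        two transcripts, one sequence  1b
isoform_mix               three isoforms, shared blocks  1a, 2a, 2b
duplicated_locus          two genes, identical product   3a
cross_locus               two genes sharing one block    1a, 3b
========================  =============================  ================

PSM counts per gene and condition are negative-binomial with mean
proportional to abundance times the number of theoretical peptides;
decoy hits are injected at a configurable fraction with a separate score
distribution.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .db import ProteinRecord, SequenceDB, build_decoy_db
from .digest import tryptic_peptides

CONSTRUCTS = (
    "single",
    "identical_isoforms",
    "isoform_mix",
    "duplicated_locus",
    "cross_locus",
)

#: genes consumed by each construct
_GENES_NEEDED = {
    "single": 1,
    "identical_isoforms": 1,
    "isoform_mix": 1,
    "duplicated_locus": 2,
    "cross_locus": 2,
}

_BLOCK_ALPHABET = "ACDEFGHILMNQSTVWY"  # no K/R (cleavage) and no P (Keil rule)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreModel:
    target_loc: float = 6.0
    target_scale: float = 1.0
    decoy_loc: float = 0.0
    decoy_scale: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 30
    block_len: int = 30
    blocks_per_protein: int = 4
    p_identical_isoform: float = 0.15
    p_duplicated_locus: float = 0.1
    abundance_mu: float = 3.0  # log-normal parameters of per-gene abundance
    abundance_sigma: float = 1.0
    fold_changes: tuple = (("gene:G0001", float("-inf")),)
    psm_rate: float = 1.0  # mean PSMs per theoretical peptide per abundance unit
    decoy_psm_fraction: float = 0.01
    score_model: ScoreModel = field(default_factory=ScoreModel)
    dispersion: float = 0.05
    seed: int = 0
    conditions: tuple = ("fed", "starved")

    def validate(self) -> None:
        for name in ("p_identical_isoform", "p_duplicated_locus",
                     "decoy_psm_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 7:
            raise ConfigError(
                "n_genes must be >= 7 to realize every construct "
                "(the two-locus constructs consume two gene models each)"
            )
        if self.block_len < 7 or self.block_len > 50:
            raise ConfigError("block_len must be in [7, 50] to survive the "
                              "default peptide length filter")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")


@dataclass
class GroundTruth:
    genes: pd.DataFrame  # gene_id, construct, abundance per condition, log2fc
    peptide_classes: dict  # theoretical block peptide -> expected class
    construct_of: dict  # gene_id -> construct


def _new_block(rng: np.random.Generator, config: SimConfig,
               used: set[str]) -> str:
    while True:
        body = "".join(
            rng.choice(list(_BLOCK_ALPHABET), size=config.block_len - 1)
        )
        block = body + "K"
        if block not in used:
            used.add(block)
            return block


def _expected_class(block: str, membership: dict[str, list[tuple[str, str, str]]],
                    db_records: list[ProteinRecord]) -> str:
    """Class of a block peptide from construction metadata alone."""
    entries = membership[block]
    seqs = {seq for _, _, seq in entries}
    genes = {g for g, _, _ in entries}
    if len(seqs) == 1:
        if len(genes) > 1:
            return "3a"
        (seq,) = seqs
        (gene,) = genes
        n_tr = sum(
            1 for r in db_records if r.gene_id == gene and r.sequence == seq
        )
        return "1a" if n_tr == 1 else "1b"
    if len(genes) == 1:
        (gene,) = genes
        gene_seqs = {r.sequence for r in db_records if r.gene_id == gene}
        return "2b" if seqs == gene_seqs else "2a"
    return "3b"


def simulate_db(config: SimConfig) -> tuple[SequenceDB, GroundTruth]:
    """Generate a target database realizing every construct at least once."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    used_blocks: set[str] = set()
    records: list[ProteinRecord] = []
    gene_rows = []
    construct_of: dict[str, str] = {}
    # block -> [(gene, transcript, sequence)] for definitional classification
    membership: dict[str, list[tuple[str, str, str]]] = {}

    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:04d}"

    def add_protein(gene: str, transcript: str, blocks: list[str]) -> None:
        seq = "".join(blocks)
        pid = f"P_{transcript}"
        records.append(ProteinRecord(pid, transcript, gene, seq))
        for b in blocks:
            membership.setdefault(b, []).append((gene, transcript, seq))

    def emit(construct: str) -> None:
        nb = config.blocks_per_protein
        if construct == "single":
            g = next_gene()
            add_protein(g, f"{g}.T1", [_new_block(rng, config, used_blocks)
                                       for _ in range(nb)])
            construct_of[g] = construct
        elif construct == "identical_isoforms":
            g = next_gene()
            blocks = [_new_block(rng, config, used_blocks) for _ in range(nb)]
            add_protein(g, f"{g}.T1", blocks)
            add_protein(g, f"{g}.T2", blocks)
            construct_of[g] = construct
        elif construct == "isoform_mix":
            g = next_gene()
            common = _new_block(rng, config, used_blocks)
            shared12 = _new_block(rng, config, used_blocks)
            u1, u2, u3 = (_new_block(rng, config, used_blocks) for _ in range(3))
            add_protein(g, f"{g}.T1", [common, shared12, u1])
            add_protein(g, f"{g}.T2", [common, shared12, u2])
            add_protein(g, f"{g}.T3", [common, u3])
            construct_of[g] = construct
        elif construct == "duplicated_locus":
            g1, g2 = next_gene(), next_gene()
            blocks = [_new_block(rng, config, used_blocks) for _ in range(nb)]
            add_protein(g1, f"{g1}.T1", blocks)
            add_protein(g2, f"{g2}.T1", blocks)
            construct_of[g1] = construct
            construct_of[g2] = construct
        elif construct == "cross_locus":
            g1, g2 = next_gene(), next_gene()
            shared = _new_block(rng, config, used_blocks)
            a = [_new_block(rng, config, used_blocks) for _ in range(nb - 1)]
            b = [_new_block(rng, config, used_blocks) for _ in range(nb - 1)]
            add_protein(g1, f"{g1}.T1", [shared] + a)
            add_protein(g2, f"{g2}.T1", [shared] + b)
            construct_of[g1] = construct
            construct_of[g2] = construct
        else:  # pragma: no cover
            raise ConfigError(f"unknown construct {construct!r}")

    # first pass: one of each construct, then fill randomly
    for construct in CONSTRUCTS:
        emit(construct)
    while gene_counter < config.n_genes:
        remaining = config.n_genes - gene_counter
        u = rng.random()
        if u < config.p_duplicated_locus and remaining >= 2:
            emit("duplicated_locus")
        elif u < config.p_duplicated_locus + config.p_identical_isoform:
            emit("identical_isoforms")
        else:
            choices = ["single", "isoform_mix"]
            if remaining >= 2:
                choices.append("cross_locus")
            emit(choices[rng.integers(len(choices))])

    db = SequenceDB(records)
    peptide_classes = {
        b: _expected_class(b, membership, records) for b in membership
    }

    # abundances and fold changes
    fc_of: dict[str, float] = {}
    for selector, lfc in config.fold_changes:
        kind, _, value = selector.partition(":")
        for g in construct_of:
            if (kind == "gene" and g == value) or (
                kind == "construct" and construct_of[g] == value
            ):
                fc_of[g] = float(lfc)
    cond_a, cond_b = config.conditions
    for g in sorted(construct_of):
        base = float(
            rng.lognormal(mean=config.abundance_mu, sigma=config.abundance_sigma)
        )
        lfc = fc_of.get(g, 0.0)
        if math.isinf(lfc) and lfc < 0:
            ab_a, ab_b = base, 0.0
        elif math.isinf(lfc):
            ab_a, ab_b = 0.0, base
        else:
            ab_a, ab_b = base, base * 2.0**lfc
        gene_rows.append(
            {
                "gene_id": g,
                "construct": construct_of[g],
                f"abundance_{cond_a}": ab_a,
                f"abundance_{cond_b}": ab_b,
                "log2fc": lfc,
            }
        )
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        peptide_classes=peptide_classes,
        construct_of=construct_of,
    )
    return db, truth


def _gene_peptides(db: SequenceDB, gene_id: str) -> list[str]:
    peps: list[str] = []
    seen: set[str] = set()
    for rec in db.gene_index[gene_id]:
        for tp in tryptic_peptides(rec.sequence, max_missed=0):
            if tp.sequence not in seen:
                seen.add(tp.sequence)
                peps.append(tp.sequence)
    return peps


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_psms(
    db: SequenceDB, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Draw a two-condition PSM table for a simulated target database.

    ``db`` may already contain decoy records; if not and the decoy PSM
    fraction is positive, a reversed-sequence decoy database is built
    internally to source decoy peptides.
    """
    rng = np.random.default_rng([config.seed, 1])
    sm = config.score_model
    target_db = db.target_db()
    decoys = db.decoys
    if not decoys and config.decoy_psm_fraction > 0:
        decoys = build_decoy_db(target_db, "reverse").records

    decoy_peptide_pool: list[str] = []
    for rec in decoys:
        for tp in tryptic_peptides(rec.sequence, max_missed=0):
            decoy_peptide_pool.append(tp.sequence)
    decoy_peptide_pool = sorted(set(decoy_peptide_pool))

    rows = []
    spectrum = 0
    for condition in config.conditions:
        n_target_psms = 0
        for gene_row in truth.genes.itertuples(index=False):
            gene = gene_row.gene_id
            abundance = getattr(gene_row, f"abundance_{condition}")
            peptides = _gene_peptides(target_db, gene)
            mean = abundance * len(peptides) * config.psm_rate
            count = _nb_draw(rng, mean, config.dispersion)
            if count == 0:
                continue
            split = rng.multinomial(count, np.full(len(peptides), 1 / len(peptides)))
            for pep, k in zip(peptides, split):
                for _ in range(int(k)):
                    spectrum += 1
                    rows.append(
                        {
                            "spectrum_id": f"S{spectrum:07d}",
                            "peptide": pep,
                            "score": float(rng.normal(sm.target_loc, sm.target_scale)),
                            "is_decoy": False,
                            "sample": condition,
                        }
                    )
                    n_target_psms += 1
        f = config.decoy_psm_fraction
        if f > 0 and decoy_peptide_pool:
            n_decoy = int(round(n_target_psms * f / (1 - f)))
            for _ in range(n_decoy):
                spectrum += 1
                pep = decoy_peptide_pool[int(rng.integers(len(decoy_peptide_pool)))]
                rows.append(
                    {
                        "spectrum_id": f"S{spectrum:07d}",
                        "peptide": pep,
                        "score": float(rng.normal(sm.decoy_loc, sm.decoy_scale)),
                        "is_decoy": True,
                        "sample": condition,
                    }
                )
    return pd.DataFrame(
        rows, columns=["spectrum_id", "peptide", "score", "is_decoy", "sample"]
    )
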