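"""Condition-overlap summaries, candidate-cytokine filtering, category
tallies, and end-to-end pipeline orchestration."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import UNEQUIVOCAL_CLASSES, classify_psms
from .db import SequenceDB, build_decoy_db, concat_dbs, write_fasta_db
from .diffexp import diff_expression
from .fdr import choose_cutoff, multilevel_fdr
from .infer import groups_to_frame, identification_summary, infer_proteins
from .simulate import SimConfig, simulate_db, simulate_psms

logger = logging.getLogger("hemoshotgun")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class OverlapSummary:
    """Two-condition detection overlap (Venn arithmetic)."""

    both: int
    only_a: int
    only_b: int

    @property
    def total_a(self) -> int:
        return self.both + self.only_a

    @property
    def total_b(self) -> int:
        return self.both + self.only_b

    @property
    def union_total(self) -> int:
        return self.both + self.only_a + self.only_b

    def percentages(self) -> dict[str, float]:
        n = self.union_total
        if n == 0:
            return {"both": 0.0, "only_a": 0.0, "only_b": 0.0}
        return {
            "both": 100.0 * self.both / n,
            "only_a": 100.0 * self.only_a / n,
            "only_b": 100.0 * self.only_b / n,
        }


def condition_overlap(counts: pd.DataFrame, min_count: int = 1) -> OverlapSummary:
    """Detection overlap between the two sample columns of a count matrix.

    A gene model is detected in a condition when its count reaches
    ``min_count`` (default: any nonzero count).
    """
    if counts.shape[1] != 2:
        raise ValueError("expected exactly two sample columns")
    a = counts.iloc[:, 0].to_numpy() >= min_count
    b = counts.iloc[:, 1].to_numpy() >= min_count
    return OverlapSummary(
        both=int((a & b).sum()),
        only_a=int((a & ~b).sum()),
        only_b=int((~a & b).sum()),
    )


def cytokine_candidates(
    annotations: pd.DataFrame,
    detected_ids: set[str] | None = None,
    max_len: int = 400,
) -> list[str]:
    """Secreted globular proteins below the length cutoff, not yet known.

    Retains rows with a signal peptide, globular fold, length strictly
    below ``max_len``, and no prior report; sorted by id.  When
    ``detected_ids`` is given, ids without an annotation row trigger a
    warning and are skipped.
    """
    if detected_ids is not None:
        missing = detected_ids - set(annotations["id"])
        if missing:
            warnings.warn(
                f"{len(missing)} detected gene models lack annotation rows; skipped"
            )
        annotations = annotations[annotations["id"].isin(detected_ids)]
    keep = (
        annotations["signal_peptide"].astype(bool)
        & annotations["globular"].astype(bool)
        & (annotations["length"] < max_len)
        & ~annotations["previously_known"].astype(bool)
    )
    return sorted(annotations.loc[keep, "id"])


def category_peptide_counts(
    classified: pd.DataFrame, category_map: dict[str, str]
) -> pd.DataFrame:
    """Distinct unequivocal peptides (classes 1a/1b/3a) per label and sample.

    Gene models not in ``category_map`` are ignored.  Peptides spanning
    several genes (3a) count toward each mapped gene's label.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    uneq = classified[
        classified["evidence_class"].isin(UNEQUIVOCAL_CLASSES)
        & ~classified["is_decoy"].astype(bool)
    ]
    for rec in uneq.itertuples(index=False):
        for gene in rec.gene_ids.split(";"):
            label = category_map.get(gene)
            if label is None:
                continue
            rows.setdefault((label, rec.sample), set()).add(rec.peptide)
    return pd.DataFrame(
        [
            {"category": label, "sample": sample, "n_peptides": len(peps)}
            for (label, sample), peps in sorted(rows.items())
        ],
        columns=["category", "sample", "n_peptides"],
    )


def spectral_counts(classified: pd.DataFrame, conditions: tuple) -> pd.DataFrame:
    """Gene-model x condition PSM counts from unambiguous gene attributions.

    Only target PSMs whose peptide implies a single gene model
    (classes 1a/1b/2a/2b) are counted.
    """
    sub = classified[
        ~classified["is_decoy"].astype(bool)
        & ~classified["gene_ids"].str.contains(";")
    ]
    table = (
        sub.groupby(["gene_ids", "sample"]).size().unstack(fill_value=0)
    )
    for cond in conditions:
        if cond not in table.columns:
            table[cond] = 0
    table = table[list(conditions)].astype(int)
    table.index.name = "gene_id"
    table.columns.name = None
    return table.sort_index()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g", lineterminator="\n")


def run_pipeline(config: SimConfig, out_dir: str | Path, max_fdr: float = 0.002,
                 min_psms: int = 2, decile: float = 0.1) -> dict:
    """Simulate, classify, infer, estimate FDR, test differential abundance.

    Writes every artifact as TSV/FASTA under ``out_dir`` plus a key-value
    manifest; returns the artifacts in memory.  Fully deterministic under
    the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def stage(name: str, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    def _simulate():
        target_db, truth = simulate_db(config)
        decoy_db = build_decoy_db(target_db, "reverse")
        full_db = concat_dbs(target_db, decoy_db)
        psms = simulate_psms(full_db, truth, config)
        write_fasta_db(full_db, out / "db.fasta")
        _write_tsv(psms, out / "psms.tsv")
        _write_tsv(truth.genes, out / "ground_truth.tsv")
        return full_db, truth, psms

    full_db, truth, psms = stage("simulate", _simulate)
    artifacts["db"], artifacts["truth"], artifacts["psms"] = full_db, truth, psms

    def _filter():
        cut = choose_cutoff(psms, max_fdr=max_fdr)
        accepted = psms[psms["score"] >= cut.threshold].reset_index(drop=True)
        return cut, accepted

    cut, accepted = stage("score-filter", _filter)
    artifacts["cutoff"] = cut

    classified = stage("classify", lambda: classify_psms(accepted, full_db))
    _write_tsv(classified, out / "classified.tsv")
    artifacts["classified"] = classified

    def _infer():
        is_decoy = classified["is_decoy"].astype(bool)
        tgt = infer_proteins(classified[~is_decoy], full_db, min_psms=min_psms)
        dec = infer_proteins(classified[is_decoy], full_db, min_psms=min_psms)
        return tgt, dec

    target_groups, decoy_groups = stage("infer", _infer)
    _write_tsv(groups_to_frame(target_groups), out / "groups.tsv")
    _write_tsv(groups_to_frame(decoy_groups), out / "decoy_groups.tsv")
    artifacts["groups"] = target_groups
    artifacts["decoy_groups"] = decoy_groups

    is_decoy = classified["is_decoy"].astype(bool)
    census = stage(
        "census",
        lambda: identification_summary(
            target_groups, classified[~is_decoy],
            decoy_groups, classified[is_decoy],
        ),
    )
    _write_tsv(census, out / "census.tsv")
    artifacts["census"] = census

    estimates = stage(
        "fdr",
        lambda: multilevel_fdr(classified, len(target_groups), len(decoy_groups)),
    )
    fdr_table = pd.DataFrame(
        [
            {"level": e.level, "n_target": e.n_target, "n_decoy": e.n_decoy,
             "fdr": e.fdr}
            for e in estimates.values()
        ]
    )
    _write_tsv(fdr_table, out / "fdr.tsv")
    artifacts["fdr"] = estimates

    counts = stage(
        "counts", lambda: spectral_counts(classified, config.conditions)
    )
    _write_tsv(counts, out / "counts.tsv", index=True)
    artifacts["counts"] = counts

    def _diffexp():
        res = diff_expression(counts, *config.conditions, decile=decile)
        return res

    diff = stage("diffexp", _diffexp)
    _write_tsv(diff.table, out / "diffexp.tsv")
    ma = diff.table[["id", "base_mean", "log2fc", "top_decile", "direction"]]
    _write_tsv(ma, out / "ma_plot.tsv")
    artifacts["diffexp"] = diff

    overlap = stage("overlap", lambda: condition_overlap(counts))
    pct = overlap.percentages()
    overlap_table = pd.DataFrame(
        [
            {"set": "both", "n": overlap.both, "pct_of_union": pct["both"]},
            {"set": f"{config.conditions[0]}_only", "n": overlap.only_a,
             "pct_of_union": pct["only_a"]},
            {"set": f"{config.conditions[1]}_only", "n": overlap.only_b,
             "pct_of_union": pct["only_b"]},
            {"set": f"{config.conditions[0]}_total", "n": overlap.total_a,
             "pct_of_union": float("nan")},
            {"set": f"{config.conditions[1]}_total", "n": overlap.total_b,
             "pct_of_union": float("nan")},
        ]
    )
    _write_tsv(overlap_table, out / "overlap.tsv")
    artifacts["overlap"] = overlap

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_genes": config.n_genes,
        "max_fdr": max_fdr,
        "min_psms": min_psms,
        "decile": decile,
        "score_cutoff": f"{cut.threshold:.8g}",
        "cutoff_warning": cut.warning,
        "n_psms_simulated": len(psms),
        "n_psms_accepted": len(accepted),
        "n_target_groups": len(target_groups),
        "n_decoy_groups": len(decoy_groups),
        "normalization_caveat": diff.normalization_caveat,
    }
    with open(out / "manifest.txt", "w") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}={value}\n")
    artifacts["manifest"] = manifest
    return artifacts
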