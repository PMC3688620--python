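"""Target-decoy false-discovery-rate estimation and cutoff selection.

The estimator is decoys/targets at each of three levels: spectra (PSMs),
distinct peptide sequences, and protein(-group) identifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class FdrError(ValueError):
    pass


@dataclass(frozen=True)
class FdrEstimate:
    level: str  # spectrum | peptide | protein
    n_target: int
    n_decoy: int

    @property
    def fdr(self) -> float:
        return estimate_fdr(self.n_target, self.n_decoy)


def estimate_fdr(n_target: int, n_decoy: int) -> float:
    """Decoy-over-target FDR estimate; 0/0 is defined as 0."""
    if n_target < 0 or n_decoy < 0:
        raise FdrError("counts must be non-negative")
    if n_target == 0:
        if n_decoy == 0:
            return 0.0
        raise FdrError("FDR undefined: decoy hits without target hits")
    return n_decoy / n_target


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    fdr: float
    n_target: int
    n_decoy: int
    warning: bool  # True when no threshold attains the requested FDR


def choose_cutoff(
    psms: pd.DataFrame, max_fdr: float = 0.002, score_column: str = "score"
) -> CutoffResult:
    """Smallest score threshold whose accepted-set FDR is <= ``max_fdr``.

    Acceptance is ``score >= threshold`` (ties accepted).  If no candidate
    threshold qualifies, the maximal observed score is returned with
    ``warning=True``.
    """
    if psms.empty:
        raise FdrError("empty PSM table")
    sub = psms[["score", "is_decoy"]].copy() if score_column == "score" else (
        psms[[score_column, "is_decoy"]].rename(columns={score_column: "score"})
    )
    sub = sub.sort_values("score", ascending=False, kind="mergesort")
    n_target = (~sub["is_decoy"].astype(bool)).cumsum().to_numpy()
    n_decoy = sub["is_decoy"].astype(bool).cumsum().to_numpy()
    scores = sub["score"].to_numpy()

    best: CutoffResult | None = None
    for i in range(len(sub) - 1, -1, -1):
        # candidate threshold scores[i] accepts rows 0..last index with same score
        if i + 1 < len(sub) and scores[i + 1] == scores[i]:
            continue  # not a boundary between distinct scores
        t_count, d_count = int(n_target[i]), int(n_decoy[i])
        if t_count == 0 and d_count > 0:
            continue
        fdr = estimate_fdr(t_count, d_count)
        if fdr <= max_fdr:
            best = CutoffResult(float(scores[i]), fdr, t_count, d_count, False)
            break
    if best is not None:
        return best
    top = float(scores[0])
    mask = scores >= top
    t_count = int((~sub["is_decoy"].astype(bool).to_numpy()[mask]).sum())
    d_count = int(sub["is_decoy"].astype(bool).to_numpy()[mask].sum())
    fdr = d_count / t_count if t_count else float("nan")
    return CutoffResult(top, fdr, t_count, d_count, True)


def multilevel_fdr(
    classified: pd.DataFrame,
    n_target_groups: int,
    n_decoy_groups: int,
) -> dict[str, FdrEstimate]:
    """Spectrum-, peptide- and protein-level estimates from one analysis.

    ``classified`` is the accepted PSM table (targets and decoys);
    protein-level counts come from running inference identically on the
    two populations.
    """
    is_decoy = classified["is_decoy"].astype(bool)
    targets = classified[~is_decoy]
    decoys = classified[is_decoy]
    return {
        "spectrum": FdrEstimate("spectrum", len(targets), len(decoys)),
        "peptide": FdrEstimate(
            "peptide",
            targets["peptide"].nunique() if len(targets) else 0,
            decoys["peptide"].nunique() if len(decoys) else 0,
        ),
        "protein": FdrEstimate("protein", n_target_groups, n_decoy_groups),
    }
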