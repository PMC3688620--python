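"""Parsimonious protein and protein-group inference from classified peptides.

Inference is staged by information content:

1. every identical-sequence class supported by an unequivocal peptide
   (1a/1b/3a) becomes an identification;
2. every gene model supported by a not-yet-explained 2a/2b peptide becomes
   a gene-model group;
3. 3b peptides contained in an existing identification are absorbed; the
   rest are explained by a minimum-cardinality set cover over
   containment-pattern protein classes.

Reported groups must reach a minimum PSM support (default 2); dropping an
under-supported group re-runs orphan coverage to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .classify import CLASS_PRIORITY, UNEQUIVOCAL_CLASSES, class_census
from .db import SequenceDB


class InferenceError(ValueError):
    pass


@dataclass
class ProteinGroup:
    group_id: str
    member_protein_ids: frozenset[str]
    implied_gene_ids: frozenset[str]
    evidence_tier: str  # unambiguous | gene-model | cover
    supporting_peptides: set[str] = field(default_factory=set)
    psm_count: int = 0
    best_class: str = "3b"
    cover_algorithm: str = ""

    def sort_key(self) -> tuple:
        tier_order = {"unambiguous": 0, "gene-model": 1, "cover": 2}
        return (tier_order[self.evidence_tier], tuple(sorted(self.member_protein_ids)))


def _peptide_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Collapse PSMs to distinct peptides with containment sets and counts."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        first = sub.iloc[0]
        return pd.Series(
            {
                "evidence_class": first["evidence_class"],
                "proteins": frozenset(first["protein_ids"].split(";")),
                "genes": frozenset(first["gene_ids"].split(";")),
                "n_psms": len(sub),
            }
        )

    if classified.empty:
        return pd.DataFrame(
            columns=["peptide", "evidence_class", "proteins", "genes", "n_psms"]
        )
    out = (
        classified.groupby("peptide", sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def minimal_cover(
    candidates_by_peptide: dict[str, set[frozenset[str]]],
    exact_limit: int = 20,
) -> tuple[list[frozenset[str]], str]:
    """Minimum-cardinality set of candidate groups covering every peptide.

    A candidate group covers a peptide when it appears in that peptide's
    candidate set.  Exhaustive search (by increasing cover size, first hit
    in lexicographic order of sorted member tuples) when the number of
    distinct candidates is at most ``exact_limit``; greedy
    largest-coverage-first beyond.  Returns (cover, algorithm-name).
    """
    for pep, cands in candidates_by_peptide.items():
        if not cands:
            raise InferenceError(f"no candidate group for peptide {pep!r}")
    universe = list(candidates_by_peptide)
    all_cands = sorted(
        {c for cands in candidates_by_peptide.values() for c in cands},
        key=lambda c: tuple(sorted(c)),
    )
    if not universe:
        return [], "exact"

    def covers(chosen: tuple[frozenset[str], ...]) -> bool:
        chosen_set = set(chosen)
        return all(candidates_by_peptide[p] & chosen_set for p in universe)

    if len(all_cands) <= exact_limit:
        for k in range(1, len(all_cands) + 1):
            for combo in combinations(all_cands, k):
                if covers(combo):
                    return list(combo), "exact"
        raise InferenceError("unreachable: full candidate set does not cover")

    uncovered = set(universe)
    chosen: list[frozenset[str]] = []
    coverage = {
        c: {p for p in universe if c in candidates_by_peptide[p]} for c in all_cands
    }
    while uncovered:
        gain = {c: len(coverage[c] & uncovered) for c in all_cands}
        top = max(gain.values())
        best = min(
            (c for c in all_cands if gain[c] == top),
            key=lambda c: tuple(sorted(c)),
        )
        chosen.append(best)
        uncovered -= coverage[best]
    return chosen, "greedy"


def infer_proteins(
    classified: pd.DataFrame,
    db: SequenceDB,
    min_psms: int = 2,
) -> list[ProteinGroup]:
    """Build the minimal identification list from one classified population.

    ``classified`` holds PSMs of a single population (targets or decoys)
    annotated by :func:`hemoshotgun.classify.classify_psms`.  Peptide
    support is overlapping: a peptide supports every group containing it.
    """
    if min_psms < 1:
        raise InferenceError("min_psms must be >= 1")
    peptides = _peptide_table(classified)
    if peptides.empty:
        return []
    prot2gene = {r.protein_id: r.gene_id for r in db.records}

    # stage 1: unequivocal peptides -> identical-sequence-class identifications
    groups: dict[frozenset[str], ProteinGroup] = {}
    uneq = peptides[peptides["evidence_class"].isin(UNEQUIVOCAL_CLASSES)]
    for row in uneq.itertuples(index=False):
        key = row.proteins
        if key not in groups:
            groups[key] = ProteinGroup(
                group_id="",
                member_protein_ids=key,
                implied_gene_ids=frozenset(prot2gene[p] for p in key),
                evidence_tier="unambiguous",
            )

    # stage 2: 2a/2b peptides not explained by stage 1 -> gene-model groups
    def explained(prots: frozenset[str]) -> bool:
        return any(prots & g.member_protein_ids for g in groups.values())

    gene_members: dict[str, set[str]] = {}
    gm = peptides[peptides["evidence_class"].isin({"2a", "2b"})]
    for row in gm.itertuples(index=False):
        if explained(row.proteins):
            continue
        (gene,) = row.genes
        gene_members.setdefault(gene, set()).update(row.proteins)
    for gene in sorted(gene_members):
        key = frozenset(gene_members[gene])
        if key not in groups:
            groups[key] = ProteinGroup(
                group_id="",
                member_protein_ids=key,
                implied_gene_ids=frozenset({gene}),
                evidence_tier="gene-model",
            )

    # stage 3 + min_psms fixed point
    banned: set[frozenset[str]] = set()
    base_keys = set(groups)
    pep_rows = list(peptides.itertuples(index=False))
    cover_algorithm = ""
    for _ in range(len(groups) + len(peptides) + 1):
        active = {k: g for k, g in groups.items() if k not in banned}

        orphans = {}
        for row in pep_rows:
            if row.evidence_class != "3b":
                continue
            if any(row.proteins & k for k in active):
                continue
            cands = {
                frozenset({p}) for p in row.proteins
            }
            cands = {c for c in cands if c not in banned}
            if cands:
                orphans[row.peptide] = cands
        if orphans:
            # candidate unit: proteins collapsed by identical containment pattern
            pattern: dict[str, frozenset[str]] = {}
            for pep, cands in orphans.items():
                for c in cands:
                    (p,) = c
                    pattern.setdefault(p, frozenset())
            for p in pattern:
                pattern[p] = frozenset(
                    pep for pep, cands in orphans.items()
                    if frozenset({p}) in cands
                )
            # group proteins sharing a pattern into one candidate class
            by_pattern: dict[frozenset[str], set[str]] = {}
            for p, pat in pattern.items():
                by_pattern.setdefault(pat, set()).add(p)
            unit_of = {
                p: frozenset(members)
                for pat, members in by_pattern.items()
                for p in members
            }
            cand_map = {
                pep: {unit_of[p] for c in cands for p in c}
                for pep, cands in orphans.items()
            }
            cand_map = {
                pep: {c for c in cands if c not in banned}
                for pep, cands in cand_map.items()
            }
            # orphans whose every candidate was banned stay unreported
            cand_map = {pep: c for pep, c in cand_map.items() if c}
            cover, cover_algorithm = (
                minimal_cover(cand_map) if cand_map else ([], "exact")
            )
            for key in cover:
                if key not in groups:
                    groups[key] = ProteinGroup(
                        group_id="",
                        member_protein_ids=key,
                        implied_gene_ids=frozenset(prot2gene[p] for p in key),
                        evidence_tier="cover",
                        cover_algorithm=cover_algorithm,
                    )
                active[key] = groups[key]

        # absorb: a peptide supports every active group intersecting it
        for g in active.values():
            g.supporting_peptides = set()
            g.psm_count = 0
            g.best_class = "3b"
        for row in pep_rows:
            for g in active.values():
                if row.proteins & g.member_protein_ids:
                    g.supporting_peptides.add(row.peptide)
                    g.psm_count += row.n_psms
                    if CLASS_PRIORITY[row.evidence_class] < CLASS_PRIORITY[g.best_class]:
                        g.best_class = row.evidence_class

        weak = [k for k, g in active.items() if g.psm_count < min_psms]
        if not weak:
            final = sorted(active.values(), key=ProteinGroup.sort_key)
            for i, g in enumerate(final, start=1):
                g.group_id = f"GRP{i:04d}"
            return final
        banned.update(weak)
        # cover groups must be recomputed against the reduced active set
        for k in list(groups):
            if k not in base_keys:
                if groups[k].evidence_tier == "cover" and k not in banned:
                    del groups[k]
    raise InferenceError("min_psms fixed point not reached")  # pragma: no cover


def groups_to_frame(groups: list[ProteinGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "evidence_tier": [g.evidence_tier for g in groups],
            "best_class": [g.best_class for g in groups],
            "members": [";".join(sorted(g.member_protein_ids)) for g in groups],
            "genes": [";".join(sorted(g.implied_gene_ids)) for g in groups],
            "n_peptides": [len(g.supporting_peptides) for g in groups],
            "n_psms": [g.psm_count for g in groups],
            "cover_algorithm": [g.cover_algorithm for g in groups],
        }
    )


def identification_summary(
    groups: list[ProteinGroup],
    classified: pd.DataFrame,
    decoy_groups: list[ProteinGroup] | None = None,
    decoy_classified: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Census in the six-class shape plus target/decoy total rows.

    Each group is counted once, in the row of its most informative
    supporting peptide class, so the per-class protein column sums to the
    reported total.
    """
    census = class_census(classified).set_index("evidence_class")
    census["n_proteins"] = 0
    for g in groups:
        census.loc[g.best_class, "n_proteins"] += 1
    totals = {
        "evidence_class": "target_total",
        "n_spectra": int(census["n_spectra"].sum()),
        "n_peptides": int(census["n_peptides"].sum()),
        "n_proteins": len(groups),
    }
    rows = census.reset_index().to_dict("records") + [totals]
    if decoy_classified is not None:
        rows.append(
            {
                "evidence_class": "decoy_total",
                "n_spectra": len(decoy_classified),
                "n_peptides": decoy_classified["peptide"].nunique()
                if len(decoy_classified)
                else 0,
                "n_proteins": len(decoy_groups or []),
            }
        )
    return pd.DataFrame(rows)
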