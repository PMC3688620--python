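"""In-silico tryptic digestion and monoisotopic peptide mass computation.

Cleavage is C-terminal to K/R, suppressed before proline (Keil rule,
configurable off).  Fully tryptic peptides span up to a configured number
of missed cleavage sites; semi-tryptic peptides retain exactly one tryptic
terminus.  Masses are monoisotopic with a fixed carbamidomethyl shift on
cysteine and optional methionine oxidation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Monoisotopic residue masses, Da (Unimod/expasy values, 5-decimal precision).
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565

CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915


class DigestError(ValueError):
    """Invalid digestion or mass-computation input."""


@dataclass(frozen=True)
class ModificationSpec:
    """Fixed and variable mass shifts keyed by residue."""

    fixed: dict = field(default_factory=lambda: {"C": CARBAMIDOMETHYL})
    variable: dict = field(default_factory=lambda: {"M": OXIDATION})
    water_mass: float = WATER_MONO


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    missed_cleavages: int
    semitryptic: bool
    mass: float


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions *after* which trypsin cleaves (K/R, not before P)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def tryptic_peptides(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    include_semi: bool = False,
    proline_rule: bool = True,
    mods: ModificationSpec | None = None,
) -> list[TheoreticalPeptide]:
    """Enumerate tryptic (and optionally semi-tryptic) peptides.

    Duplicate sequences are collapsed keeping the minimal missed-cleavage
    annotation; a sequence attainable fully tryptically is never flagged
    semi-tryptic.  Output is ordered by position of first occurrence.
    """
    if not sequence:
        raise DigestError("empty protein sequence")
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise DigestError(f"non-amino-acid characters {sorted(bad)} in sequence")
    if max_missed < 0:
        raise DigestError("max_missed must be >= 0")
    mods = mods or ModificationSpec()

    sites = cleavage_sites(sequence, proline_rule)
    # Fragment boundaries: [start, end) for minimal (0-missed) fragments.
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    n_frag = len(bounds) - 1

    best: dict[str, tuple[int, bool]] = {}
    order: list[str] = []

    def consider(pep: str, missed: int, semi: bool) -> None:
        if not (min_len <= len(pep) <= max_len):
            return
        if pep not in best:
            best[pep] = (missed, semi)
            order.append(pep)
        else:
            m0, s0 = best[pep]
            best[pep] = (min(m0, missed), s0 and semi)

    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = bounds[i], bounds[j + 1]
            span = sequence[start:end]
            consider(span, j - i, False)
            if include_semi:
                # one non-tryptic terminus: trim from either end, keep the other
                for cut in range(1, len(span)):
                    internal = len(cleavage_sites(span[cut:], proline_rule))
                    consider(span[cut:], internal, True)
                    internal = len(cleavage_sites(span[:cut], proline_rule))
                    consider(span[:cut], internal, True)

    out = []
    for pep in order:
        missed, semi = best[pep]
        if missed > max_missed:
            continue
        out.append(
            TheoreticalPeptide(
                sequence=pep,
                missed_cleavages=missed,
                semitryptic=semi,
                mass=peptide_mass(pep, mods),
            )
        )
    return out


def peptide_mass(
    sequence: str,
    mods: ModificationSpec | None = None,
    oxidized_positions: set[int] | frozenset[int] = frozenset(),
) -> float:
    """Monoisotopic peptide mass with fixed mods applied everywhere and
    variable mods applied at ``oxidized_positions`` (0-based)."""
    mods = mods or ModificationSpec()
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in sequence) + mods.water_mass
    except KeyError as exc:
        raise DigestError(f"unknown residue {exc.args[0]!r}") from None
    for aa, shift in mods.fixed.items():
        mass += shift * sequence.count(aa)
    for pos in oxidized_positions:
        if pos < 0 or pos >= len(sequence):
            raise DigestError(f"oxidation position {pos} out of range")
        aa = sequence[pos]
        if aa not in mods.variable:
            raise DigestError(f"variable modification not defined for {aa!r}")
        mass += mods.variable[aa]
    return mass


def match_mass(
    observed: float, candidates: list[TheoreticalPeptide], tol: float = 0.04
) -> list[TheoreticalPeptide]:
    """Candidates whose mass lies within ``tol`` Da of the observed mass."""
    if tol <= 0:
        raise DigestError("mass tolerance must be positive")
    return [c for c in candidates if abs(c.mass - observed) <= tol]
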