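"""One-locus, three-allele genetics of emergence timing.

Timing strains are encoded at a single locus with alleles ``F`` (fortnightly,
semilunar emergence), ``M1`` (monthly, full-moon weeks) and ``M2`` (monthly,
new-moon weeks).  Homozygotes express their own strain's rhythm.  Because the
two monthly strains never co-emerge, ``M1M2`` heterozygotes cannot be produced
by within-tide mating; the five remaining genotypes are the permitted ones.

Heterozygotes carrying ``F`` express the monthly rhythm when ``F`` is recessive
(the default dominance structure) and the fortnightly rhythm when ``F`` is
dominant.  Cross-strain (hybrid) eggs hatch with reduced viability ``gamma``,
which is how maladaptive hybrid timing enters the model: as a viability cost,
not as an explicit intermediate phenotype.

Mendelian bookkeeping is exact (rational arithmetic); there is no per-offspring
stochasticity in the main engine.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping

import numpy as np

#: the three alleles, in canonical order
ALLELES: tuple[str, ...] = ("F", "M1", "M2")

#: the five permitted genotypes, in canonical order (engine array axis order)
GENOTYPES: tuple[str, ...] = ("FF", "FM1", "FM2", "M1M1", "M2M2")

#: the disallowed monthly-x-monthly heterozygote (tracked only as discarded mass)
M1M2: str = "M1M2"

ALL_GENOTYPES: tuple[str, ...] = GENOTYPES + (M1M2,)

#: emergence phenotypes (same labels as the strains)
PHENOTYPES: tuple[str, ...] = ("F", "M1", "M2")

DOMINANCE_MODES: tuple[str, ...] = ("F_recessive", "F_dominant")

_ALLELE_PAIRS: dict[str, tuple[str, str]] = {
    "FF": ("F", "F"),
    "FM1": ("F", "M1"),
    "FM2": ("F", "M2"),
    "M1M1": ("M1", "M1"),
    "M2M2": ("M2", "M2"),
    "M1M2": ("M1", "M2"),
}

GENOTYPE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GENOTYPES)}
ALLELE_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}


def genotype_from_alleles(a: str, b: str) -> str:
    """Canonical (unordered) genotype label for an allele pair."""
    if a not in ALLELE_INDEX or b not in ALLELE_INDEX:
        raise ValueError(f"unknown allele in pair ({a!r}, {b!r})")
    first, second = sorted((a, b), key=ALLELE_INDEX.__getitem__)
    return first + second


def alleles_of(genotype: str) -> tuple[str, str]:
    try:
        return _ALLELE_PAIRS[genotype]
    except KeyError:
        raise ValueError(f"unknown genotype {genotype!r}") from None


def is_hybrid(genotype: str) -> bool:
    """True iff the two alleles differ (cross-strain genotype)."""
    a, b = alleles_of(genotype)
    return a != b


def phenotype_of(genotype: str, dominance: str = "F_recessive") -> str:
    """Emergence phenotype of a permitted genotype under the dominance rule.

    Homozygotes express their own strain.  ``FM1``/``FM2`` heterozygotes
    express the monthly rhythm under ``F_recessive`` and the fortnightly
    rhythm under ``F_dominant``.  The ``M1M2`` genotype has no defined
    phenotype (it is never produced under the default dominance structure)
    and raises.
    """
    if dominance not in DOMINANCE_MODES:
        raise ValueError(f"unknown dominance mode {dominance!r}")
    if genotype == M1M2:
        raise ValueError("M1M2 genotype has no defined emergence phenotype")
    a, b = alleles_of(genotype)
    if a == b:
        return a
    # every permitted heterozygote carries exactly one F allele
    monthly = b if a == "F" else a
    return "F" if dominance == "F_dominant" else monthly


def offspring_distribution(mother: str, sire: str) -> dict[str, Fraction]:
    """Exact Mendelian offspring genotype proportions for a cross.

    Gametes segregate 1/2 : 1/2; proportions are exact rationals and sum to 1
    *before* any viability weighting.  The distribution may include ``M1M2``
    (e.g. from FM1 x M2M2 crosses, possible only when F is dominant); whether
    that mass is viable is decided downstream.
    """
    ma, mb = alleles_of(mother)
    sa, sb = alleles_of(sire)
    dist: dict[str, Fraction] = {}
    for ga in (ma, mb):
        for gb in (sa, sb):
            off = genotype_from_alleles(ga, gb)
            dist[off] = dist.get(off, Fraction(0)) + Fraction(1, 4)
    return dist


def egg_viability(genotype: str, gamma: float) -> float:
    """Hatching viability of an egg: 1 for pure-strain, ``gamma`` for hybrids."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma if is_hybrid(genotype) else 1.0


def allele_frequencies(counts: Mapping[str, float]) -> dict[str, float]:
    """Allele frequencies from per-genotype (non-negative) masses.

    f(A) = (2 x homozygote(A) + sum of heterozygotes carrying A) / (2 x total).
    Raises on zero total mass (the caller decides how to treat extinction).
    """
    allele_mass = dict.fromkeys(ALLELES, 0.0)
    total = 0.0
    for g, n in counts.items():
        if n < 0:
            raise ValueError(f"negative mass for genotype {g!r}")
        a, b = alleles_of(g)
        allele_mass[a] += n
        allele_mass[b] += n
        total += n
    if total <= 0:
        raise ValueError("zero total mass: allele frequencies undefined")
    return {a: allele_mass[a] / (2.0 * total) for a in ALLELES}


# ---------------------------------------------------------------------------
# numpy tables used by the weekly engine (genotype axis ordered as GENOTYPES)
# ---------------------------------------------------------------------------

def allele_count_matrix() -> np.ndarray:
    """(5, 3) array: copies of each allele carried by each permitted genotype."""
    mat = np.zeros((len(GENOTYPES), len(ALLELES)))
    for i, g in enumerate(GENOTYPES):
        for a in alleles_of(g):
            mat[i, ALLELE_INDEX[a]] += 1
    return mat


def mendelian_table() -> np.ndarray:
    """(5, 5, 6) array of Mendelian proportions, offspring axis = ALL_GENOTYPES.

    ``table[mother, sire, offspring]`` with the sixth offspring slot holding
    any M1M2 mass.
    """
    idx = {g: i for i, g in enumerate(ALL_GENOTYPES)}
    table = np.zeros((len(GENOTYPES), len(GENOTYPES), len(ALL_GENOTYPES)))
    for i, mother in enumerate(GENOTYPES):
        for j, sire in enumerate(GENOTYPES):
            for off, frac in offspring_distribution(mother, sire).items():
                table[i, j, idx[off]] = float(frac)
    return table


def viability_vector(gamma: float, dominance: str = "F_recessive") -> np.ndarray:
    """(6,) viability weights over ALL_GENOTYPES.

    Pure-strain eggs hatch fully, F-carrying hybrids with probability
    ``gamma``.  M1M2 eggs are assigned viability 0: the monthly strains'
    mating niches never overlap, so the model treats any Mendelian M1M2 mass
    (possible only under F dominance) as inviable rather than invent a
    phenotype for it.
    """
    weights = np.array([egg_viability(g, gamma) for g in GENOTYPES] + [0.0])
    return weights


def phenotype_codes(dominance: str = "F_recessive") -> np.ndarray:
    """(5,) int array mapping genotype index -> phenotype index in PHENOTYPES."""
    return np.array(
        [PHENOTYPES.index(phenotype_of(g, dominance)) for g in GENOTYPES]
    )


def allele_freq_vector(genotype_mass: np.ndarray) -> np.ndarray:
    """(3,) allele-frequency vector from a (5,) genotype mass vector."""
    mass = np.asarray(genotype_mass, dtype=float)
    if mass.shape != (len(GENOTYPES),):
        raise ValueError("expected a (5,) genotype mass vector")
    if np.any(mass < 0):
        raise ValueError("negative genotype mass")
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total mass: allele frequencies undefined")
    return (mass @ allele_count_matrix()) / (2.0 * total)
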