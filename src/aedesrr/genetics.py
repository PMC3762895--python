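"""Two-locus genotype algebra for the female-killing / anti-pathogen system.

The simulator tracks a female-killing (FK) locus with alleles K (transgenic)
and k (wild type) and an anti-pathogen (AP) locus with alleles A (transgenic)
and a (wild type).  The loci are autosomal and segregate independently, so a
diploid individual is one of nine genotypes.  The canonical ordering used by
every array in this package runs over decreasing A count in the outer loop
and decreasing K count in the inner loop::

    1 KKAA   2 KkAA   3 kkAA
    4 KKAa   5 KkAa   6 kkAa
    7 KKaa   8 Kkaa   9 kkaa

Everything downstream (the ODE state layout, CSV columns, metric masks) uses
this order, with 0-based positions in arrays and the 1-based ``index`` on the
:class:`Genotype` objects.

The inheritance tensor and gamete distributions are constructed in exact
rational arithmetic (:class:`fractions.Fraction`) and only converted to
floating point at the end; every probability is dyadic (denominator 16 at
worst) so the float conversion is itself exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "Genotype",
    "GAMETES",
    "N_GENOTYPES",
    "GENOTYPE_LABELS",
    "enumerate_genotypes",
    "genotype_by_label",
    "gamete_distribution",
    "inheritance_tensor_exact",
    "build_inheritance_tensor",
    "fitness_vector",
    "viability_vector",
    "allele_frequencies",
    "composite_ld",
]

#: The four gamete types, ordered (K allele, A allele) with transgenic first.
GAMETES: tuple[str, ...] = ("KA", "Ka", "kA", "ka")

N_GENOTYPES = 9

_ALLELE_CODE = {2: "KK", 1: "Kk", 0: "kk"}
_ALLELE_CODE_A = {2: "AA", 1: "Aa", 0: "aa"}


@dataclass(frozen=True)
class Genotype:
    """One of the nine two-locus genotypes.

    Attributes
    ----------
    index : int
        1-based position in the canonical ordering.
    label : str
        Four-letter genotype string, e.g. ``"KkAa"``.
    n_K : int
        Number of transgenic FK alleles (0, 1 or 2).
    n_A : int
        Number of transgenic AP alleles (0, 1 or 2).
    """

    index: int
    label: str
    n_K: int
    n_A: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@lru_cache(maxsize=1)
def enumerate_genotypes() -> tuple[Genotype, ...]:
    """Return the nine genotypes in canonical order (KKAA first, kkaa last)."""
    out = []
    idx = 1
    for n_A in (2, 1, 0):
        for n_K in (2, 1, 0):
            label = _ALLELE_CODE[n_K] + _ALLELE_CODE_A[n_A]
            out.append(Genotype(index=idx, label=label, n_K=n_K, n_A=n_A))
            idx += 1
    return tuple(out)


GENOTYPE_LABELS: tuple[str, ...] = tuple(g.label for g in enumerate_genotypes())

#: 0-based array positions of genotypes carrying no FK allele (viable females).
VIABLE_POSITIONS: tuple[int, ...] = tuple(
    g.index - 1 for g in enumerate_genotypes() if g.n_K == 0
)

#: 0-based array position of the all-wild-type genotype kkaa.
WILDTYPE_POSITION: int = 8


def genotype_by_label(label: str) -> Genotype:
    """Look up a genotype by its four-letter label."""
    for g in enumerate_genotypes():
        if g.label == label:
            return g
    raise KeyError(f"unknown genotype label {label!r}")


def gamete_distribution(g: Genotype) -> dict[str, Fraction]:
    """Exact gamete distribution produced by a parent of genotype ``g``.

    Each locus segregates independently and each parental allele is
    transmitted with probability 1/2, so the probability of passing the
    transgenic allele equals (allele count)/2 at each locus.
    """
    p_K = Fraction(g.n_K, 2)
    p_A = Fraction(g.n_A, 2)
    return {
        "KA": p_K * p_A,
        "Ka": p_K * (1 - p_A),
        "kA": (1 - p_K) * p_A,
        "ka": (1 - p_K) * (1 - p_A),
    }


def _locus_offspring_dist(c_m: int, c_n: int) -> tuple[Fraction, Fraction, Fraction]:
    """Offspring allele-count distribution at one locus.

    Parents carry ``c_m`` and ``c_n`` copies of the transgenic allele; each
    transmits it with probability c/2 independently.  Returns probabilities
    for offspring counts (0, 1, 2).
    """
    p_m = Fraction(c_m, 2)
    p_n = Fraction(c_n, 2)
    return (
        (1 - p_m) * (1 - p_n),
        p_m * (1 - p_n) + (1 - p_m) * p_n,
        p_m * p_n,
    )


@lru_cache(maxsize=1)
def inheritance_tensor_exact() -> tuple:
    """Mendelian inheritance tensor in exact rational arithmetic.

    Entry ``[i][m][n]`` is Pr(offspring genotype i | mother m, father n) for
    0-based positions in the canonical genotype order.  Built as the product
    of the per-locus offspring-count distributions, which is exact for two
    independently segregating autosomal loci.
    """
    genos = enumerate_genotypes()
    tensor = []
    for gi in genos:
        plane = []
        for gm in genos:
            row = []
            for gn in genos:
                dist_K = _locus_offspring_dist(gm.n_K, gn.n_K)
                dist_A = _locus_offspring_dist(gm.n_A, gn.n_A)
                row.append(dist_K[gi.n_K] * dist_A[gi.n_A])
            plane.append(tuple(row))
        tensor.append(tuple(plane))
    return tuple(tensor)


@lru_cache(maxsize=1)
def build_inheritance_tensor() -> np.ndarray:
    """Float inheritance tensor ``P[i, m, n]`` of shape (9, 9, 9).

    Converted from :func:`inheritance_tensor_exact`; all entries are dyadic
    rationals so the conversion is exact.  The returned array is read-only.
    """
    exact = inheritance_tensor_exact()
    arr = np.array(
        [[[float(p) for p in row] for row in plane] for plane in exact],
        dtype=float,
    )
    arr.setflags(write=False)
    return arr


def fitness_vector(c_K: float, c_A: float) -> np.ndarray:
    """Relative egg-to-larva viability of each genotype.

    Costs are additive within a locus (a heterozygote pays half the
    homozygote cost) and multiplicative across loci:

        w = (1 - c_K * n_K / 2) * (1 - c_A * n_A / 2)

    so the all-wild-type genotype always has w = 1.

    Parameters
    ----------
    c_K, c_A : float
        Homozygote fitness costs of the FK and AP transgenes, each in [0, 1].

    Raises
    ------
    ValueError
        If either cost lies outside [0, 1]; costs are rejected rather than
        clamped so configuration errors surface immediately.
    """
    for name, c in (("c_K", c_K), ("c_A", c_A)):
        if not np.isfinite(c) or c < 0.0 or c > 1.0:
            raise ValueError(f"fitness cost {name}={c!r} must lie in [0, 1]")
    genos = enumerate_genotypes()
    w = np.array(
        [(1.0 - 0.5 * c_K * g.n_K) * (1.0 - 0.5 * c_A * g.n_A) for g in genos]
    )
    return w


def viability_vector() -> np.ndarray:
    """Female emergence viability: 1 for genotypes with no FK allele, else 0.

    FK lethality acts on females at adult emergence, so only kk genotypes
    contribute emerging females.  Released transgenic females bypass this
    (they are reared with the lethal gene repressed) and enter the adult
    female compartments directly.
    """
    return np.array([1.0 if g.n_K == 0 else 0.0 for g in enumerate_genotypes()])


def _allele_count_arrays() -> tuple[np.ndarray, np.ndarray]:
    genos = enumerate_genotypes()
    return (
        np.array([g.n_K for g in genos], dtype=float),
        np.array([g.n_A for g in genos], dtype=float),
    )


def allele_frequencies(counts) -> tuple[float, float]:
    """Frequencies of the K and A alleles in a per-genotype density vector.

    Parameters
    ----------
    counts : array-like, shape (9,)
        Nonnegative densities (or counts) per genotype in canonical order.

    Returns
    -------
    (freq_K, freq_A) : tuple of float

    Raises
    ------
    ValueError
        If any count is negative or the total is zero (the frequency is then
        undefined and silently returning 0 would be misleading).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_GENOTYPES,):
        raise ValueError(f"expected 9 genotype counts, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("genotype counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("allele frequency undefined for an empty population")
    n_K, n_A = _allele_count_arrays()
    return float(n_K @ c / (2.0 * total)), float(n_A @ c / (2.0 * total))


def composite_ld(counts) -> float:
    """Burrows' composite linkage disequilibrium between the K and A loci.

    The model tracks genotypes, not gamete phase, so gametic D is not
    identifiable from the state; the composite statistic

        Delta = E[x y] / 2 - 2 p_K p_A

    (x, y the per-individual transgenic allele counts) is computable from
    genotype densities alone.  It is 0 whenever the joint genotype
    distribution factorizes across loci, and in particular for any
    monomorphic population.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_GENOTYPES,):
        raise ValueError(f"expected 9 genotype counts, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("genotype counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("composite LD undefined for an empty population")
    f = c / total
    n_K, n_A = _allele_count_arrays()
    p_K = n_K @ f / 2.0
    p_A = n_A @ f / 2.0
    e_xy = (n_K * n_A) @ f
    return float(e_xy / 2.0 - 2.0 * p_K * p_A)
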