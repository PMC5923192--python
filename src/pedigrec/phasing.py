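"""Single-site Mendelian phasing of a child against its parents.

A child's two haplotypes (paternal, maternal) are resolved site by
site from the trio genotypes alone: homozygous children are trivially
phased; heterozygous children are phased whenever exactly one
assignment of the two alleles to the parents is compatible with
Mendelian transmission (e.g. one parent homozygous).  Sites where no
assignment is compatible are flagged as Mendelian errors and left
unknown.  No population/LD information is used.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNKNOWN = -1


@dataclass
class PhasedPair:
    """Two haplotype vectors (alleles 0/1, ``-1`` unknown) for one animal.

    ``paternal``/``maternal`` name the transmitting parent when the trio
    resolves it; ``mendel_errors`` marks sites violating Mendelian
    inheritance (set unknown in both haplotypes).
    """

    paternal: np.ndarray
    maternal: np.ndarray
    mendel_errors: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.paternal.size

    @property
    def n_mendel_errors(self) -> int:
        return int(self.mendel_errors.sum())


def _can_transmit(parent: np.ndarray, allele: int) -> np.ndarray:
    """Whether each parent genotype can transmit ``allele`` (missing can)."""
    if allele == 0:
        return (parent == 0) | (parent == 1) | (parent == UNKNOWN)
    return (parent == 2) | (parent == 1) | (parent == UNKNOWN)


def phase_trio(child: np.ndarray, father: np.ndarray | None,
               mother: np.ndarray | None) -> PhasedPair:
    """Phase ``child`` against (possibly missing) parental genotypes.

    Parameters are allele-count vectors in {-1, 0, 1, 2}; ``None`` for
    an entirely ungenotyped parent.  Deterministic and idempotent.
    """
    child = np.asarray(child)
    n = child.size
    if father is None:
        father = np.full(n, UNKNOWN, dtype=np.int8)
    if mother is None:
        mother = np.full(n, UNKNOWN, dtype=np.int8)
    father = np.asarray(father)
    mother = np.asarray(mother)
    if father.size != n or mother.size != n:
        raise ValueError("trio genotype vectors differ in length")

    pat = np.full(n, UNKNOWN, dtype=np.int8)
    mat = np.full(n, UNKNOWN, dtype=np.int8)
    err = np.zeros(n, dtype=bool)

    f0, f1 = _can_transmit(father, 0), _can_transmit(father, 1)
    m0, m1 = _can_transmit(mother, 0), _can_transmit(mother, 1)

    hom0 = child == 0
    bad = hom0 & ~(f0 & m0)
    ok = hom0 & ~bad
    pat[ok] = 0
    mat[ok] = 0
    err |= bad

    hom2 = child == 2
    bad = hom2 & ~(f1 & m1)
    ok = hom2 & ~bad
    pat[ok] = 1
    mat[ok] = 1
    err |= bad

    het = child == 1
    p10 = f1 & m0          # paternal 1, maternal 0 compatible
    p01 = f0 & m1
    bad = het & ~p10 & ~p01
    err |= bad
    forced10 = het & p10 & ~p01
    pat[forced10] = 1
    mat[forced10] = 0
    forced01 = het & p01 & ~p10
    pat[forced01] = 0
    mat[forced01] = 1
    # het with both assignments possible stays unknown

    return PhasedPair(paternal=pat, maternal=mat, mendel_errors=err)


def informative_sites(donor: PhasedPair) -> np.ndarray:
    """Indices where the donor is heterozygous and fully phased.

    Exactly these sites identify which donor haplotype a transmitted
    allele came from.
    """
    pat, mat = donor.paternal, donor.maternal
    return np.flatnonzero((pat != UNKNOWN) & (mat != UNKNOWN) & (pat != mat))


def informative_mask(donor: PhasedPair) -> np.ndarray:
    pat, mat = donor.paternal, donor.maternal
    return (pat != UNKNOWN) & (mat != UNKNOWN) & (pat != mat)
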