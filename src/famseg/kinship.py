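"""KING-robust kinship estimation and pedigree verification.

The between-family robust estimator uses only genotype concordance counts
over shared non-missing biallelic sites. With N_Aa,Aa the sites heterozygous
in both samples, N_AA,aa the opposite-homozygote sites, and N_Aa(i), N_Aa(j)
the per-sample heterozygote counts:

    phi = (N_Aa,Aa - 2 N_AA,aa) / (2 min(N_Aa(i), N_Aa(j)))
          + 1/2 - (N_Aa(i) + N_Aa(j)) / (4 min(N_Aa(i), N_Aa(j)))

A duplicated sample yields phi = 0.5 exactly; first-degree relatives sit
near 0.25; unrelated pairs near 0. Inferred degrees use the estimator's
standard powers-of-two bins and are checked against the degrees expected
from the declared pedigree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import PedigreeSpec

__all__ = [
    "king_robust_kinship",
    "classify_degree",
    "pairwise_kinship",
    "KinshipResult",
    "verify_pedigree",
    "KinshipConflict",
    "DEGREE_BINS",
]

#: (lower bound on phi, label); scanned in order.
DEGREE_BINS = (
    (2 ** -1.5, "monozygotic"),  # > 0.3536
    (2 ** -2.5, "first"),        # (0.1768, 0.3536]
    (2 ** -3.5, "second"),       # (0.0884, 0.1768]
    (2 ** -4.5, "third"),        # (0.0442, 0.0884]
)


class InsufficientSitesError(ValueError):
    """Too few shared informative sites for a stable kinship estimate."""


def king_robust_kinship(
    genotypes_i: Sequence[int] | np.ndarray,
    genotypes_j: Sequence[int] | np.ndarray,
    min_sites: int = 100,
) -> float:
    """KING-robust kinship coefficient between two samples.

    Genotypes are alternate-allele doses (0/1/2); negative values mark
    missing calls and are dropped pairwise. Raises
    :class:`InsufficientSitesError` below ``min_sites`` shared sites —
    the remedy is more markers, not a looser floor.
    """
    gi = np.asarray(genotypes_i, dtype=np.int64)
    gj = np.asarray(genotypes_j, dtype=np.int64)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    shared = (gi >= 0) & (gj >= 0)
    gi, gj = gi[shared], gj[shared]
    if gi.size < min_sites:
        raise InsufficientSitesError(
            f"only {gi.size} shared non-missing sites (< {min_sites}); "
            "genotype more markers to estimate kinship"
        )
    het_i = gi == 1
    het_j = gj == 1
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    n_hethet = int((het_i & het_j).sum())
    n_opp = int((np.abs(gi - gj) == 2).sum())
    m = min(n_het_i, n_het_j)
    if m == 0:
        raise InsufficientSitesError(
            "a sample has no heterozygous calls over shared sites; "
            "kinship is undefined — add polymorphic markers"
        )
    return (n_hethet - 2.0 * n_opp) / (2.0 * m) + 0.5 - (n_het_i + n_het_j) / (4.0 * m)


def classify_degree(phi: float) -> str:
    for lower, label in DEGREE_BINS:
        if phi > lower:
            return label
    return "unrelated"


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    phi: float
    degree: str


def pairwise_kinship(
    genotypes: pd.DataFrame,
    min_sites: int = 100,
) -> list[KinshipResult]:
    """Kinship for every unordered sample pair of a sample x variant matrix."""
    samples = list(genotypes.index)
    g = genotypes.to_numpy()
    results = []
    for a, b in itertools.combinations(range(len(samples)), 2):
        phi = king_robust_kinship(g[a], g[b], min_sites=min_sites)
        results.append(
            KinshipResult((samples[a], samples[b]), phi, classify_degree(phi))
        )
    return results


@dataclass(frozen=True)
class KinshipConflict:
    pair: tuple[str, str]
    declared_degree: str
    inferred_degree: str
    phi: float
    expected_phi: float


def verify_pedigree(
    results: Sequence[KinshipResult],
    ped: PedigreeSpec,
) -> list[KinshipConflict]:
    """Compare inferred relationship degrees against the declared pedigree.

    Each estimated pair whose members are both in the pedigree is classified
    into a degree bin and checked against the bin of the pedigree-expected
    kinship coefficient. An empty list means genotype data and declared
    structure agree.
    """
    conflicts = []
    for r in results:
        a, b = r.pair
        if a not in ped or b not in ped:
            continue
        expected_phi = ped.expected_kinship(a, b)
        declared = classify_degree(expected_phi)
        if r.degree != declared:
            conflicts.append(
                KinshipConflict(
                    pair=r.pair,
                    declared_degree=declared,
                    inferred_degree=r.degree,
                    phi=r.phi,
                    expected_phi=expected_phi,
                )
            )
    return conflicts


def kinship_report(
    results: Sequence[KinshipResult],
    ped: Optional[PedigreeSpec] = None,
) -> pd.DataFrame:
    """Tabular kinship report (pair, phi, degree, conflict flag)."""
    conflicts = set()
    if ped is not None:
        conflicts = {c.pair for c in verify_pedigree(results, ped)}
    rows = [
        {
            "sample_i": r.pair[0],
            "sample_j": r.pair[1],
            "phi": r.phi,
            "degree": r.degree,
            "conflict": r.pair in conflicts,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi", "degree", "conflict"])
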