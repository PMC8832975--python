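"""Built-in study fixtures: the AF family and its three candidate variants.

The pedigree reproduces the published three-generation family with familial
atrial fibrillation: seven members with exomes (six affected carriers plus
one unaffected sibling), one affected member deceased before inclusion, and
unsequenced founders. The three candidate variants carry the published
annotation rows (CACNA1A missense, CD163L1 frameshift, OR8U1 missense) and
are planted with the co-segregation genotype pattern: heterozygous in every
sequenced affected member, absent in the unaffected sibling II-2.

MAF columns in the source table are percentages; they are stored here as
fractions (0.3526% -> 0.003526).
"""

from __future__ import annotations

import numpy as np

from .genotypes import SimVariantSpec
from .pedigree import Member, PedigreeSpec

__all__ = [
    "af_family",
    "AFFECTED_CARRIERS",
    "candidate_variants",
    "background_variants",
]

#: Sequenced affected members carrying the co-segregating variants.
AFFECTED_CARRIERS = ("II-1", "II-4", "II-5", "II-6", "III-1", "III-2")


def af_family() -> PedigreeSpec:
    """Three-generation AF pedigree with seven sequenced members."""
    M = Member
    return PedigreeSpec(
        [
            M("I-1", sex="male", affected="yes"),
            M("I-2", sex="female", affected="no"),
            M("II-1", "I-1", "I-2", sex="female", affected="yes", sequenced=True),
            M("II-2", "I-1", "I-2", sex="female", affected="no", sequenced=True),
            M("II-3", "I-1", "I-2", sex="male", affected="yes"),  # deceased
            M("II-4", "I-1", "I-2", sex="male", affected="yes", sequenced=True),
            M("II-5", "I-1", "I-2", sex="male", affected="yes", sequenced=True),
            M("II-6", "I-1", "I-2", sex="male", affected="yes", sequenced=True),
            M("II-7", sex="female", affected="no"),  # married-in
            M("III-1", "II-6", "II-7", sex="male", affected="yes", sequenced=True),
            M("III-2", "II-6", "II-7", sex="male", affected="yes", sequenced=True),
        ],
        family_id="AF1",
    )


def candidate_variants(carriers: tuple[str, ...] = AFFECTED_CARRIERS) -> list[SimVariantSpec]:
    """The three rare co-segregating candidates with published annotations."""
    return [
        SimVariantSpec(
            id="CACNA1A_19_13346442",
            role="causal",
            chrom="19", pos=13346442, ref="C", alt="T",
            gene="CACNA1A",
            gnomad_maf_by_subpop={"max": 0.0},
            d2k_maf=0.0,
            dbsnp_status="absent",
            cadd=28.0, sift="D", gerp=5.0,
            planted_carriers=carriers,
        ),
        SimVariantSpec(
            id="CD163L1_12_7521563",
            role="causal",
            chrom="12", pos=7521563, ref="TGA", alt="T",
            gene="CD163L1",
            gnomad_maf_by_subpop={"max": 0.003526},  # 0.3526 %
            d2k_maf=0.0,
            dbsnp_status="non_common",  # rs781351459
            cadd=7.034, sift=None, gerp=None,
            planted_carriers=carriers,
        ),
        SimVariantSpec(
            id="OR8U1_11_56143415",
            role="causal",
            chrom="11", pos=56143415, ref="A", alt="G",
            gene="OR8U1",
            gnomad_maf_by_subpop={"max": 0.0},
            d2k_maf=0.0,
            dbsnp_status="absent",
            cadd=0.001, sift="T", gerp=-7.1,
            planted_carriers=carriers,
        ),
    ]


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def background_variants(
    n: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.45),
    titv: float = 2.72,
    chrom: str = "1",
) -> list[SimVariantSpec]:
    """Common background SNVs for kinship estimation and filter stress tests.

    Population MAFs are uniform over ``maf_range`` and reused as the GnomAD
    and in-house annotations (so none survives the rarity screen); alleles
    are drawn with a transition bias matching a whole-exome TiTv of ``titv``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    p_transition = titv / (1.0 + titv)
    out = []
    for i in range(n):
        maf = float(rng.uniform(lo, hi))
        ref = str(rng.choice(["A", "C", "G", "T"]))
        if rng.random() < p_transition:
            alt = _TRANSITION[ref]
        else:
            alt = str(rng.choice(_TRANSVERSIONS[ref]))
        out.append(
            SimVariantSpec(
                id=f"bg{i:05d}",
                role="background",
                chrom=chrom,
                pos=100_000 + 100 * i,
                ref=ref, alt=alt,
                gene=f"GENE{i % 997}",
                gnomad_maf_by_subpop={"max": maf},
                d2k_maf=maf,
                dbsnp_status="common",
                cadd=float(rng.uniform(0, 10)),
                population_maf=maf,
            )
        )
    return out
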