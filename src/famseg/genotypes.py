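"""Pedigree genotype simulation and family-file output (VCF/PED/annotations).

Variants come in two roles. A ``causal`` variant is planted heterozygous in
an explicit carrier list and absent everywhere else — the co-segregation
pattern the downstream screen must rediscover. A ``background`` variant is
gene-dropped: founder genotypes are drawn from Hardy–Weinberg proportions at
its population allele frequency and each child receives one allele from each
parent, so every trio is Mendelian-consistent by construction.

Genotypes are coded 0/1/2 alternate-allele doses in a member x variant
``pandas.DataFrame``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .pedigree import PedigreeSpec

__all__ = [
    "SimVariantSpec",
    "simulate_pedigree_genotypes",
    "write_family_files",
    "annotation_table",
    "FamilyFiles",
]

_DBSNP = ("absent", "non_common", "common")


@dataclass(frozen=True)
class SimVariantSpec:
    """One variant to simulate, with the annotations the filters consume.

    MAF fields are fractions in [0, 0.5]. ``population_maf`` drives founder
    allele draws for background variants; ``planted_carriers`` lists the
    heterozygous members for causal variants.
    """

    id: str
    role: str  # "causal" | "background"
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "G"
    gene: str = ""
    gnomad_maf_by_subpop: dict[str, float] = field(default_factory=dict)
    d2k_maf: float = 0.0
    dbsnp_status: str = "absent"
    cadd: float = 0.0
    sift: Optional[str] = None  # "D" | "T" | None
    gerp: Optional[float] = None
    planted_carriers: tuple[str, ...] = ()
    population_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("causal", "background"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.dbsnp_status not in _DBSNP:
            raise ValueError(f"dbsnp_status must be one of {_DBSNP}")
        for name, val in [("d2k_maf", self.d2k_maf),
                          ("population_maf", self.population_maf),
                          *[(f"gnomad[{k}]", v) for k, v in self.gnomad_maf_by_subpop.items()]]:
            if not 0.0 <= val <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {val}")
        if self.role == "causal" and not self.planted_carriers:
            raise ValueError(f"causal variant {self.id!r} lists no carriers")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def gnomad_maf_max(self) -> float:
        return max(self.gnomad_maf_by_subpop.values(), default=0.0)

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "DEL" if len(self.ref) > len(self.alt) else "INS"


def simulate_pedigree_genotypes(
    ped: PedigreeSpec,
    variants: Sequence[SimVariantSpec],
    seed: int,
) -> pd.DataFrame:
    """Gene-drop ``variants`` through ``ped``; returns member x variant doses.

    Causal variants are heterozygous exactly in their planted carriers and
    hom-ref elsewhere. Background variants follow Mendelian transmission from
    founder genotypes drawn at their population allele frequency.
    Deterministic for a fixed seed.
    """
    ids = [v.id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("variant ids must be unique")
    for v in variants:
        for carrier in v.planted_carriers:
            if carrier not in ped:
                raise KeyError(
                    f"variant {v.id!r}: planted carrier {carrier!r} "
                    f"is not a member of pedigree {ped.family_id}"
                )

    rng = np.random.default_rng(seed)
    n_var = len(variants)
    maf = np.array([v.population_maf for v in variants])
    is_bg = np.array([v.role == "background" for v in variants])

    doses: dict[str, np.ndarray] = {}
    for m in ped.topological_order():
        g = np.zeros(n_var, dtype=np.int64)
        if is_bg.any():
            if m.father_id is None and m.mother_id is None:
                g[is_bg] = rng.binomial(2, maf[is_bg])
            else:
                # one allele from each parent (missing parent = founder draw)
                for pid in (m.father_id, m.mother_id):
                    if pid is not None:
                        p = doses[pid][is_bg] / 2.0
                    else:
                        p = maf[is_bg]
                    g[is_bg] += rng.binomial(1, p)
        doses[m.id] = g

    table = pd.DataFrame.from_dict(doses, orient="index", columns=ids)
    table = table.loc[[m.id for m in ped.members]]
    for j, v in enumerate(variants):
        if v.role == "causal":
            col = np.zeros(len(ped.members), dtype=np.int64)
            carriers = set(v.planted_carriers)
            col[[i for i, m in enumerate(ped.members) if m.id in carriers]] = 1
            table.iloc[:, j] = col
    table.index.name = "member"
    return table


# -- family files ----------------------------------------------------------

@dataclass(frozen=True)
class FamilyFiles:
    vcf: Path
    ped: Path
    annotations: Path


def annotation_table(variants: Sequence[SimVariantSpec]) -> pd.DataFrame:
    """Per-variant annotation table in the on-disk column layout."""
    rows = []
    for v in variants:
        rows.append(
            {
                "variant_id": v.id,
                "gene": v.gene or "NA",
                "gnomad_maf_max_subpop": v.gnomad_maf_max,
                "d2k_maf": v.d2k_maf,
                "dbsnp_status": v.dbsnp_status,
                "cadd": v.cadd,
                "sift": v.sift if v.sift is not None else "NA",
                "gerp": v.gerp if v.gerp is not None else "NA",
            }
        )
    columns = ["variant_id", "gene", "gnomad_maf_max_subpop", "d2k_maf",
               "dbsnp_status", "cadd", "sift", "gerp"]
    return pd.DataFrame(rows, columns=columns)


_CODE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_family_files(
    genotypes: pd.DataFrame,
    ped: PedigreeSpec,
    variants: Sequence[SimVariantSpec],
    out_dir: str | Path,
    prefix: str = "family",
) -> FamilyFiles:
    """Write a VCF v4.2 (sequenced members only), a 6-column PED file and a
    tab-separated annotation table; the trio round-trips through
    :func:`famseg.prioritize.read_family` losslessly.
    """
    from .pedigree import write_ped  # local import to avoid cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = ped.sequenced_ids
    missing = [s for s in samples if s not in genotypes.index]
    if missing:
        raise ValueError(f"genotype table lacks sequenced members: {missing}")

    header = pysam.VariantHeader()
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    for c in contigs:
        header.contigs.add(c, length=260_000_000)
    for s in samples:
        header.add_sample(s)

    vcf_path = out_dir / f"{prefix}.vcf"
    order = sorted(range(len(variants)),
                   key=lambda i: (contigs.index(variants[i].chrom), variants[i].pos))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for i in order:
            v = variants[i]
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1,
                alleles=(v.ref, v.alt), id=v.id,
            )
            for s in samples:
                rec.samples[s]["GT"] = _CODE_TO_GT[int(genotypes.at[s, v.id])]
            vf.write(rec)

    ped_path = write_ped(ped, out_dir / f"{prefix}.ped")
    ann_path = out_dir / f"{prefix}.annotations.tsv"
    annotation_table(variants).to_csv(ann_path, sep="\t", index=False)
    return FamilyFiles(vcf=vcf_path, ped=ped_path, annotations=ann_path)
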