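"""Family-based rare-variant prioritization.

The screen mirrors standard practice for a dominant familial phenotype:

1. **Rarity** — a variant passes if its maximum GnomAD subpopulation MAF is
   below 0.01% *or* its in-house cohort MAF is below one allele in 2x1972
   exomes, *and* it is absent or "non-common" in dbSNP.
2. **Co-segregation** — every sequenced affected member must carry at least
   one alternate allele (het or hom-alt: dominant model) and, by default, no
   sequenced unaffected member may carry it.
3. **Ranking** — survivors are ordered by CADD descending, ties broken by
   GERP descending then variant id.

Inputs are a multi-sample VCF, a PED file and a tab-separated annotation
table keyed by variant id. MAFs are fractions throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .pedigree import PedigreeSpec, read_ped

__all__ = [
    "Annotation",
    "VariantRecord",
    "FilterCriteria",
    "FilterResult",
    "read_family",
    "rarity_filter",
    "cosegregation_filter",
    "prioritize",
    "PrioritizationResult",
    "titv_ratio",
    "TiTvResult",
]

GENOTYPE_CODES = {"homref": 0, "het": 1, "homalt": 2, "missing": -1}


class FamilyFileError(ValueError):
    """Raised for malformed or inconsistent family input files."""


@dataclass(frozen=True)
class Annotation:
    """Per-variant annotations consumed (never computed) by the filters."""

    gene: str = ""
    gnomad_maf_max: Optional[float] = None
    d2k_maf: Optional[float] = None
    dbsnp_status: str = "absent"
    cadd: Optional[float] = None
    sift: Optional[str] = None
    gerp: Optional[float] = None
    constraint_z: Optional[float] = None
    pli: Optional[float] = None


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-sample genotype doses (0/1/2, -1 missing)."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, int]
    annotation: Optional[Annotation] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def variant_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "DEL" if len(self.ref) > len(self.alt) else "INS"


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the rarity and co-segregation screens (fractions)."""

    gnomad_max_maf: float = 1e-4  # 0.01 %
    inhouse_max_maf: float = 1.0 / (2 * 1972)
    dbsnp_allowed: frozenset[str] = frozenset({"absent", "non_common"})
    require_all_affected: bool = True
    exclude_unaffected_carriers: bool = True
    missing_genotype_policy: str = "fail"  # "fail" | "ignore-member"
    missing_annotation_policy: str = "fail"  # "fail" | "pass"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gnomad_max_maf <= 1.0:
            raise ValueError("gnomad_max_maf must be in [0, 1]")
        if not 0.0 <= self.inhouse_max_maf <= 1.0:
            raise ValueError("inhouse_max_maf must be in [0, 1]")
        if self.missing_genotype_policy not in ("fail", "ignore-member"):
            raise ValueError("missing_genotype_policy must be 'fail' or 'ignore-member'")
        if self.missing_annotation_policy not in ("fail", "pass"):
            raise ValueError("missing_annotation_policy must be 'fail' or 'pass'")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...] = ()
    evidence: tuple[tuple[str, int, str], ...] = ()  # (member, dose, status)

    def __bool__(self) -> bool:
        return self.passed


# -- readers ---------------------------------------------------------------

def _split_record(variant, samples: list[str]) -> list[VariantRecord]:
    """Split a (possibly multi-allelic) VCF record into biallelic records."""
    records = []
    alts = variant.ALT
    gts = variant.genotypes  # [[a1, a2, phased], ...]
    for ai, alt in enumerate(alts, start=1):
        doses = {}
        for s, gt in zip(samples, gts):
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                doses[s] = -1
            else:
                doses[s] = sum(1 for a in alleles if a == ai)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
        if len(alts) > 1:
            vid = f"{vid}:alt{ai}"
        records.append(
            VariantRecord(
                id=vid,
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=variant.REF,
                alt=alt,
                genotypes=doses,
            )
        )
    return records


def _parse_optional_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    if isinstance(x, str) and x.strip().upper() in ("NA", "", "."):
        return None
    return float(x)


def read_annotations(path: str | Path) -> dict[str, Annotation]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    except pd.errors.EmptyDataError:
        return {}
    required = {"variant_id", "gnomad_maf_max_subpop", "d2k_maf", "dbsnp_status", "cadd"}
    missing = required - set(df.columns)
    if missing:
        raise FamilyFileError(f"annotation table lacks columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        sift = d.get("sift")
        if isinstance(sift, float) and math.isnan(sift):
            sift = None
        if isinstance(sift, str) and sift.upper() == "NA":
            sift = None
        out[d["variant_id"]] = Annotation(
            gene=str(d.get("gene", "") or ""),
            gnomad_maf_max=_parse_optional_float(d.get("gnomad_maf_max_subpop")),
            d2k_maf=_parse_optional_float(d.get("d2k_maf")),
            dbsnp_status=str(d["dbsnp_status"]),
            cadd=_parse_optional_float(d.get("cadd")),
            sift=sift,
            gerp=_parse_optional_float(d.get("gerp")),
            constraint_z=_parse_optional_float(d.get("constraint_z")),
            pli=_parse_optional_float(d.get("pli")),
        )
    return out


def read_family(
    vcf_path: str | Path,
    ped_path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[PedigreeSpec, list[VariantRecord]]:
    """Read VCF + PED (+ annotation TSV) into a pedigree and variant records.

    Multi-allelic records are split into biallelic ones. Every VCF sample
    must appear in the PED file; sequenced status is inferred from VCF
    membership. Variants without an annotation row keep ``annotation=None``
    and are handled by the filter's missing-annotation policy.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    ped = read_ped(ped_path)
    extra = [s for s in samples if s not in ped]
    if extra:
        raise FamilyFileError(
            f"VCF samples absent from PED file: {extra}"
        )
    ped = ped.with_sequenced(samples)
    annotations = read_annotations(annotation_path) if annotation_path else {}
    records: list[VariantRecord] = []
    lineno = 0
    try:
        for variant in vcf:
            lineno += 1
            records.extend(_split_record(variant, samples))
    except Exception as exc:  # cyvcf2 raises plain Exception subclasses
        raise FamilyFileError(
            f"malformed VCF record near data line {lineno + 1} of {vcf_path}: {exc}"
        ) from exc
    if annotations:
        records = [
            VariantRecord(
                id=r.id, chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                genotypes=r.genotypes,
                annotation=annotations.get(r.id),
            )
            for r in records
        ]
    return ped, records


def genotype_matrix(records: Sequence[VariantRecord], samples: Sequence[str]) -> pd.DataFrame:
    """Sample x variant dose matrix (-1 for missing calls)."""
    data = {r.id: [r.genotypes.get(s, -1) for s in samples] for r in records}
    return pd.DataFrame(data, index=list(samples))


# -- filters ---------------------------------------------------------------

def rarity_filter(v: VariantRecord, criteria: FilterCriteria | None = None) -> FilterResult:
    """Pass iff (GnomAD max-subpop MAF < threshold OR in-house MAF <
    threshold) AND the dbSNP status is allowed."""
    c = criteria or FilterCriteria()
    ann = v.annotation
    if ann is None or (ann.gnomad_maf_max is None and ann.d2k_maf is None):
        if c.missing_annotation_policy == "pass":
            return FilterResult(True, ("unannotated",))
        return FilterResult(False, ("unannotated",))
    reasons = []
    gnomad_ok = ann.gnomad_maf_max is not None and ann.gnomad_maf_max < c.gnomad_max_maf
    inhouse_ok = ann.d2k_maf is not None and ann.d2k_maf < c.inhouse_max_maf
    if not gnomad_ok:
        reasons.append("gnomad_maf")
    if not inhouse_ok:
        reasons.append("inhouse_maf")
    maf_ok = gnomad_ok or inhouse_ok
    dbsnp_ok = ann.dbsnp_status in c.dbsnp_allowed
    if not dbsnp_ok:
        reasons.append("dbsnp_status")
    if maf_ok and dbsnp_ok:
        return FilterResult(True)
    if maf_ok:
        # only the dbSNP clause failed
        reasons = [r for r in reasons if r == "dbsnp_status"]
    return FilterResult(False, tuple(reasons))


def cosegregation_filter(
    v: VariantRecord,
    ped: PedigreeSpec,
    criteria: FilterCriteria | None = None,
) -> FilterResult:
    """Dominant-model co-segregation across the sequenced pedigree members.

    Pass iff every sequenced affected member carries >= 1 alternate allele
    and (by default) no sequenced unaffected member carries it. Members
    without exomes never contribute. A missing genotype in an affected
    member fails conservatively unless the policy is ``ignore-member``.
    """
    c = criteria or FilterCriteria()
    reasons: list[str] = []
    evidence: list[tuple[str, int, str]] = []
    for mid in ped.sequenced_ids:
        status = ped.member(mid).affected
        dose = v.genotypes.get(mid, -1)
        evidence.append((mid, dose, status))
        if status == "yes" and c.require_all_affected:
            if dose < 0:
                if c.missing_genotype_policy == "fail":
                    reasons.append(f"missing-genotype:{mid}")
            elif dose == 0:
                reasons.append(f"absent-in-affected:{mid}")
        elif status == "no" and c.exclude_unaffected_carriers:
            if dose > 0:
                reasons.append(f"carrier-unaffected:{mid}")
    return FilterResult(not reasons, tuple(reasons), tuple(evidence))


_RANK_COLUMNS = [
    "variant_id", "gene", "chrom", "pos", "ref", "alt", "type",
    "gnomad_maf_max_subpop", "d2k_maf", "dbsnp_status",
    "cadd", "sift", "gerp", "constraint_z", "pli",
]


@dataclass
class PrioritizationResult:
    candidates: pd.DataFrame  # ranked survivors
    audit: pd.DataFrame  # every variant with pass/fail flags and reasons

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def _variant_row(v: VariantRecord) -> dict:
    ann = v.annotation or Annotation()
    return {
        "variant_id": v.id,
        "gene": ann.gene or "NA",
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "type": v.variant_type,
        "gnomad_maf_max_subpop": ann.gnomad_maf_max,
        "d2k_maf": ann.d2k_maf,
        "dbsnp_status": ann.dbsnp_status,
        "cadd": ann.cadd,
        "sift": ann.sift,
        "gerp": ann.gerp,
        "constraint_z": ann.constraint_z,
        "pli": ann.pli,
    }


def prioritize(
    variants: Sequence[VariantRecord],
    ped: PedigreeSpec,
    criteria: FilterCriteria | None = None,
) -> PrioritizationResult:
    """Run rarity + co-segregation screens and rank survivors by CADD.

    Ties are broken by GERP descending, then variant id, so the ranking is
    a total order stable under input permutation.
    """
    c = criteria or FilterCriteria()
    audit_rows = []
    survivors = []
    for v in variants:
        rare = rarity_filter(v, c)
        coseg = cosegregation_filter(v, ped, c)
        row = _variant_row(v)
        row["rarity_pass"] = rare.passed
        row["cosegregation_pass"] = coseg.passed
        row["reasons"] = ";".join((*rare.reasons, *coseg.reasons)) or "."
        audit_rows.append(row)
        if rare.passed and coseg.passed:
            survivors.append(row)

    def rank_key(row: dict):
        cadd = row["cadd"] if row["cadd"] is not None else -math.inf
        gerp = row["gerp"] if row["gerp"] is not None else -math.inf
        return (-cadd, -gerp, row["variant_id"])

    survivors.sort(key=rank_key)
    cand = pd.DataFrame(survivors, columns=_RANK_COLUMNS + ["rarity_pass", "cosegregation_pass", "reasons"])
    cand.insert(0, "rank", np.arange(1, len(cand) + 1))
    audit = pd.DataFrame(audit_rows, columns=_RANK_COLUMNS + ["rarity_pass", "cosegregation_pass", "reasons"])
    return PrioritizationResult(candidates=cand, audit=audit)


# -- QC --------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class TiTvResult:
    transitions: int
    transversions: int

    @property
    def defined(self) -> bool:
        return self.transitions + self.transversions > 0

    @property
    def ratio(self) -> float:
        if not self.defined:
            return math.nan
        if self.transversions == 0:
            return math.inf
        return self.transitions / self.transversions


def titv_ratio(variants: Sequence[VariantRecord]) -> TiTvResult:
    """Transition/transversion ratio over the SNVs of a call set.

    Non-SNVs are ignored. With no transversions the ratio is ``inf``; with
    no SNVs at all it is ``nan`` and ``defined`` is False.
    """
    ti = tv = 0
    for v in variants:
        if v.variant_type != "SNV":
            continue
        pair = (v.ref.upper(), v.alt.upper())
        if pair[0] not in _BASES or pair[1] not in _BASES:
            continue
        if pair in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    return TiTvResult(ti, tv)
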