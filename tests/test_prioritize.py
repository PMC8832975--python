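"""Rarity and co-segregation screens, ranking, and the TiTv QC statistic."""

import math
import random

import numpy as np

from famseg.examples import AFFECTED_CARRIERS, af_family, background_variants, candidate_variants
from famseg.genotypes import simulate_pedigree_genotypes, write_family_files
from famseg.pedigree import Member, PedigreeSpec
from famseg.prioritize import (
    Annotation,
    FilterCriteria,
    VariantRecord,
    cosegregation_filter,
    prioritize,
    rarity_filter,
    read_family,
    titv_ratio,
)


def _record(vid="v", ann=None, genotypes=None, ref="A", alt="G"):
    return VariantRecord(
        id=vid, chrom="1", pos=100, ref=ref, alt=alt,
        genotypes=genotypes or {}, annotation=ann,
    )


class TestRarityFilter:
    def test_novel_variant_passes(self):
        ann = Annotation(gnomad_maf_max=0.0, d2k_maf=0.0, dbsnp_status="absent")
        assert rarity_filter(_record(ann=ann)).passed

    def test_inhouse_clause_rescues_gnomad_common(self):
        """A variant at 0.3526% in GnomAD still passes via the in-house
        cohort clause when absent there (the OR in the criterion)."""
        ann = Annotation(gnomad_maf_max=0.003526, d2k_maf=0.0,
                         dbsnp_status="non_common")
        res = rarity_filter(_record(ann=ann))
        assert res.passed

    def test_common_everywhere_fails_with_both_maf_reasons(self):
        ann = Annotation(gnomad_maf_max=0.01, d2k_maf=0.01, dbsnp_status="absent")
        res = rarity_filter(_record(ann=ann))
        assert not res.passed
        assert set(res.reasons) == {"gnomad_maf", "inhouse_maf"}

    def test_dbsnp_common_fails(self):
        ann = Annotation(gnomad_maf_max=0.0, d2k_maf=0.0, dbsnp_status="common")
        res = rarity_filter(_record(ann=ann))
        assert not res.passed
        assert res.reasons == ("dbsnp_status",)

    def test_unannotated_fails_by_default_configurable(self):
        res = rarity_filter(_record(ann=None))
        assert not res.passed and res.reasons == ("unannotated",)
        loose = FilterCriteria(missing_annotation_policy="pass")
        assert rarity_filter(_record(ann=None), loose).passed


class TestCosegregationFilter:
    def _geno(self, carriers, missing=(), family=None):
        fam = family or af_family()
        g = {}
        for mid in fam.sequenced_ids:
            g[mid] = -1 if mid in missing else (1 if mid in carriers else 0)
        return g

    def test_full_cosegregation_passes(self, family):
        g = self._geno(AFFECTED_CARRIERS, family=family)
        res = cosegregation_filter(_record(genotypes=g), family)
        assert res.passed
        assert len(res.evidence) == 7

    def test_unaffected_carrier_fails(self, family):
        g = self._geno(AFFECTED_CARRIERS + ("II-2",), family=family)
        res = cosegregation_filter(_record(genotypes=g), family)
        assert not res.passed
        assert any("carrier-unaffected:II-2" in r for r in res.reasons)

    def test_absent_in_one_affected_fails(self, family):
        carriers = tuple(c for c in AFFECTED_CARRIERS if c != "III-2")
        res = cosegregation_filter(_record(genotypes=self._geno(carriers, family=family)), family)
        assert not res.passed
        assert any("absent-in-affected:III-2" in r for r in res.reasons)

    def test_missing_genotype_policy(self, family):
        g = self._geno(AFFECTED_CARRIERS, missing=("II-4",), family=family)
        res = cosegregation_filter(_record(genotypes=g), family)
        assert not res.passed
        assert any(r.startswith("missing-genotype") for r in res.reasons)
        lenient = FilterCriteria(missing_genotype_policy="ignore-member")
        assert cosegregation_filter(_record(genotypes=g), family, lenient).passed

    def test_agrees_with_brute_force_enumeration(self):
        """Oracle equivalence: on random small families and random genotype
        patterns the filter matches an independent member-by-member check."""
        rng = random.Random(13)
        criteria = FilterCriteria()
        for trial in range(60):
            n = rng.randint(2, 8)
            members = []
            for i in range(n):
                members.append(
                    Member(
                        f"m{i}",
                        sex=rng.choice(["male", "female"]),
                        affected=rng.choice(["yes", "no", "unknown"]),
                        sequenced=rng.random() < 0.8,
                    )
                )
            ped = PedigreeSpec(members, family_id="R")
            g = {m.id: rng.choice([-1, 0, 0, 1, 1, 2]) for m in members if m.sequenced}
            got = cosegregation_filter(_record(genotypes=g), ped, criteria).passed

            # brute force: enumerate every member independently
            ok = True
            for m in members:
                if not m.sequenced:
                    continue
                dose = g[m.id]
                if m.affected == "yes" and dose in (0, -1):
                    ok = False
                if m.affected == "no" and dose in (1, 2):
                    ok = False
            assert got == ok, f"trial {trial}"


class TestPrioritize:
    def test_worked_example_three_survivors_ranked_by_cadd(self, family, candidates, family_genotypes, tmp_path):
        """The three planted rare co-segregating variants all survive, with
        the CACNA1A missense ranked first at CADD 28."""
        files = write_family_files(family_genotypes, family, candidates, tmp_path)
        ped, records = read_family(files.vcf, files.ped, files.annotations)
        result = prioritize(records, ped)
        assert result.n_candidates == 3
        genes = list(result.candidates["gene"])
        assert genes == ["CACNA1A", "CD163L1", "OR8U1"]
        assert list(result.candidates["cadd"]) == [28.0, 7.034, 0.001]

    def test_empty_input_gives_empty_table(self, family):
        result = prioritize([], family)
        assert result.n_candidates == 0
        assert list(result.candidates.columns)[:2] == ["rank", "variant_id"]

    def test_single_causal_among_common_background(self, family, tmp_path):
        """1000 common background variants plus one planted rare causal
        variant -> exactly one survivor, verified by exhaustive re-check."""
        variants = candidate_variants()[0:1] + background_variants(1000, seed=31, maf_range=(0.01, 0.45))
        genotypes = simulate_pedigree_genotypes(family, variants, seed=32)
        files = write_family_files(genotypes, family, variants, tmp_path)
        ped, records = read_family(files.vcf, files.ped, files.annotations)
        result = prioritize(records, ped)
        assert result.n_candidates == 1
        assert result.candidates.iloc[0]["gene"] == "CACNA1A"
        # exhaustive oracle over the audit table
        audit = result.audit
        survivors = audit[audit.rarity_pass & audit.cosegregation_pass]
        assert len(survivors) == 1

    def test_ranking_stable_under_permutation(self, family, candidates, family_genotypes):
        records = []
        for v in candidates:
            records.append(
                VariantRecord(
                    id=v.id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    genotypes={s: int(family_genotypes.at[s, v.id]) for s in family.sequenced_ids},
                    annotation=Annotation(
                        gene=v.gene, gnomad_maf_max=v.gnomad_maf_max,
                        d2k_maf=v.d2k_maf, dbsnp_status=v.dbsnp_status,
                        cadd=v.cadd, sift=v.sift, gerp=v.gerp,
                    ),
                )
            )
        a = prioritize(records, family).candidates
        b = prioritize(records[::-1], family).candidates
        assert list(a["variant_id"]) == list(b["variant_id"])

    def test_maf_threshold_monotonicity(self, family, candidates, family_genotypes):
        """Loosening a MAF threshold never removes a survivor; tightening
        never adds one."""
        records = []
        rng = np.random.default_rng(5)
        for i in range(40):
            mafs = float(rng.uniform(0, 0.01))
            records.append(
                _record(
                    vid=f"r{i}",
                    ann=Annotation(gnomad_maf_max=mafs, d2k_maf=float(rng.uniform(0, 0.01)),
                                   dbsnp_status="absent", cadd=float(i)),
                    genotypes={s: 1 if s in AFFECTED_CARRIERS else 0
                               for s in family.sequenced_ids},
                )
            )
        thresholds = [1e-5, 1e-4, 1e-3, 1e-2]
        survivor_sets = []
        for thr in thresholds:
            crit = FilterCriteria(gnomad_max_maf=thr, inhouse_max_maf=thr)
            ids = set(prioritize(records, family, crit).candidates["variant_id"])
            survivor_sets.append(ids)
        for tight, loose in zip(survivor_sets, survivor_sets[1:]):
            assert tight <= loose


class TestTiTv:
    def test_enumerable_example(self):
        recs = [
            _record("a", ref="A", alt="G"),
            _record("b", ref="C", alt="T"),
            _record("c", ref="A", alt="C"),
        ]
        res = titv_ratio(recs)
        assert (res.transitions, res.transversions) == (2, 1)
        assert res.ratio == 2.0

    def test_indel_only_undefined(self):
        res = titv_ratio([_record("d", ref="TGA", alt="T")])
        assert not res.defined
        assert math.isnan(res.ratio)

    def test_no_transversions_flagged_infinite(self):
        res = titv_ratio([_record("a", ref="A", alt="G")])
        assert res.ratio == math.inf

    def test_uniform_random_snvs_near_half(self):
        """Uniformly random SNVs: 4 of 12 ordered base pairs are transitions,
        so TiTv -> 4/8 = 0.5 within 3 binomial SEs at n=10,000."""
        rng = np.random.default_rng(17)
        bases = "ACGT"
        recs = []
        for i in range(10_000):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            recs.append(_record(f"s{i}", ref=str(ref), alt=str(alt)))
        res = titv_ratio(recs)
        p = res.transitions / 10_000
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        assert abs(p - 1 / 3) < 3 * se
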