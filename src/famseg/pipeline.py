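"""End-to-end reproducible run: genetics stage + electrophysiology stage.

``run_all`` simulates the built-in AF family (three planted candidate
variants plus common background variants), writes and re-reads the family
files, verifies relatedness, runs the prioritization screen, then simulates
WT and variant-channel cohorts under the configured protocols, fits every
cell and writes group comparisons. Everything is seeded; two runs with the
same config and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channel import channel_preset
from .cohort import CohortSpec, generate_cohort, write_cohort
from .examples import af_family, background_variants, candidate_variants
from .genotypes import simulate_pedigree_genotypes, write_family_files
from .kinship import kinship_report, pairwise_kinship, verify_pedigree
from .prioritize import FilterCriteria, genotype_matrix, prioritize, read_family, titv_ratio
from .stats import compare_groups

__all__ = ["RunConfig", "GroupConfig", "run_all"]

logger = logging.getLogger("famseg")


@dataclass
class GroupConfig:
    """Cohort sizes for one channel group; defaults mirror the published
    per-protocol cell counts."""

    preset: str = "wt"
    n_iv: int = 32
    n_ssi: int = 20
    n_slow: int = 26

    def n_for(self, protocol: str) -> int:
        return {"iv": self.n_iv, "ssi": self.n_ssi, "slow_inact": self.n_slow}[protocol]


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "famseg_run"
    n_background_variants: int = 2000
    background_maf_range: tuple[float, float] = (0.05, 0.45)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    groups: dict[str, GroupConfig] = field(
        default_factory=lambda: {
            "WT": GroupConfig(preset="wt", n_iv=32, n_ssi=20, n_slow=26),
            "V1686M": GroupConfig(preset="v1686m", n_iv=25, n_ssi=18, n_slow=24),
        }
    )
    protocols: tuple[str, ...] = ("iv", "ssi", "slow_inact")
    write_sweeps: bool = False  # per-cell traces are bulky; tables suffice

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"]["dbsnp_allowed"] = sorted(self.criteria.dbsnp_allowed)
        d["background_maf_range"] = list(self.background_maf_range)
        d["protocols"] = list(self.protocols)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "criteria" in d and not isinstance(d["criteria"], FilterCriteria):
            c = dict(d["criteria"])
            if "dbsnp_allowed" in c:
                c["dbsnp_allowed"] = frozenset(c["dbsnp_allowed"])
            d["criteria"] = FilterCriteria(**c)
        if "groups" in d:
            d["groups"] = {
                name: g if isinstance(g, GroupConfig) else GroupConfig(**g)
                for name, g in d["groups"].items()
            }
        if "background_maf_range" in d:
            d["background_maf_range"] = tuple(d["background_maf_range"])
        if "protocols" in d:
            d["protocols"] = tuple(d["protocols"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _setup_logging(out_dir: Path, verbose: bool) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return handler


def _genetics_stage(cfg: RunConfig, out: Path, seed: int) -> None:
    ped = af_family()
    variants = candidate_variants() + background_variants(
        cfg.n_background_variants, seed=seed, maf_range=cfg.background_maf_range
    )
    genotypes = simulate_pedigree_genotypes(ped, variants, seed=seed + 1)
    files = write_family_files(genotypes, ped, variants, out, prefix="family")
    logger.info(
        "genetics: wrote %s (%s), %s, %s",
        files.vcf.name, _digest(files.vcf), files.ped.name, files.annotations.name,
    )
    ped_r, records = read_family(files.vcf, files.ped, files.annotations)

    titv = titv_ratio(records)
    logger.info(
        "genetics: %d variants read; TiTv = %.3f (%d ti / %d tv)",
        len(records), titv.ratio, titv.transitions, titv.transversions,
    )

    gm = genotype_matrix(records, ped_r.sequenced_ids)
    kin = pairwise_kinship(gm)
    conflicts = verify_pedigree(kin, ped_r)
    kinship_report(kin, ped_r).to_csv(out / "kinship.tsv", sep="\t", index=False, float_format="%.6g")
    logger.info(
        "kinship: %d pairs estimated, %d conflict(s) with declared pedigree",
        len(kin), len(conflicts),
    )

    result = prioritize(records, ped_r, cfg.criteria)
    result.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
    result.audit.to_csv(out / "filter_audit.tsv", sep="\t", index=False, float_format="%.6g")
    n_rare = int(result.audit["rarity_pass"].sum())
    n_coseg = int(result.audit["cosegregation_pass"].sum())
    logger.info(
        "prioritize: %d/%d pass rarity, %d pass co-segregation, %d candidates",
        n_rare, len(result.audit), n_coseg, result.n_candidates,
    )
    if result.n_candidates:
        top = result.candidates.iloc[0]
        logger.info(
            "prioritize: top candidate %s (%s), CADD %s",
            top["variant_id"], top["gene"], top["cadd"],
        )


def _ephys_stage(cfg: RunConfig, out: Path, seed: int) -> None:
    from .ephys import fit_table  # deferred: scipy-heavy

    if not cfg.groups:
        logger.warning("ephys: no cohorts configured; stage skipped")
        return
    ss_root = np.random.SeedSequence(seed)
    group_tables = {}
    names = sorted(cfg.groups)
    for gi, name in enumerate(names):
        gcfg = cfg.groups[name]
        frames = []
        for pi, protocol in enumerate(cfg.protocols):
            n = gcfg.n_for(protocol)
            if n < 1:
                logger.warning("ephys: %s/%s has n < 1; skipped", name, protocol)
                continue
            spec = CohortSpec(
                n_cells=n,
                params=channel_preset(gcfg.preset),
                seed=int(ss_root.generate_state(1)[0] % 2**31) + 1000 * gi + pi,
                group=name,
            )
            cells = generate_cohort(spec, protocol)
            if cfg.write_sweeps:
                write_cohort(cells, out / "sweeps" / name)
            frames.append(fit_table(cells))
            logger.info("ephys: %s/%s simulated and fitted (n=%d)", name, protocol, n)
        if not frames:
            logger.warning("ephys: group %s produced no cells; skipped", name)
            continue
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(out / f"fits_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        group_tables[name] = table

    if len(group_tables) != 2:
        logger.warning("ephys: need exactly 2 groups for comparison, have %d", len(group_tables))
        return
    (name_a, ta), (name_b, tb) = sorted(group_tables.items())
    rows = []
    for qty in ("peak_density", "vrev", "v50_act", "v50_inact", "tau_inact"):
        xa = ta[qty].dropna().to_numpy()
        xb = tb[qty].dropna().to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            continue
        gs = compare_groups(xa, xb, qty, mode="t_test", group_names=(name_a, name_b))
        rows.append(
            {
                "quantity": qty,
                "test": gs.test,
                f"{name_a}_mean": gs.groups[0].mean,
                f"{name_a}_sem": gs.groups[0].sem,
                f"{name_a}_n": gs.groups[0].n,
                f"{name_b}_mean": gs.groups[1].mean,
                f"{name_b}_sem": gs.groups[1].sem,
                f"{name_b}_n": gs.groups[1].n,
                "statistic": gs.statistic,
                "p_value": gs.p_value,
            }
        )
        logger.info(
            "compare %s: %s %.4g±%.2g (n=%d) vs %s %.4g±%.2g (n=%d), p=%.4g",
            qty, name_a, gs.groups[0].mean, gs.groups[0].sem, gs.groups[0].n,
            name_b, gs.groups[1].mean, gs.groups[1].sem, gs.groups[1].n, gs.p_value,
        )
    pd.DataFrame(rows).to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")


def run_all(cfg: RunConfig, verbose: bool = False) -> Path:
    """Run both stages into ``cfg.out_dir``; returns the run directory.

    Idempotent for a fixed seed. The fully resolved config is written next
    to the outputs; the log records the package version, seed and input
    digests plus one summary line per filter decision.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, verbose)
    try:
        logger.info("famseg %s, seed %d", __version__, cfg.seed)
        cfg.to_yaml(out / "resolved_config.yaml")
        try:
            _genetics_stage(cfg, out, cfg.seed)
        except Exception as exc:
            raise RuntimeError(f"genetics stage failed: {exc}") from exc
        try:
            _ephys_stage(cfg, out, cfg.seed + 7919)
        except Exception as exc:
            raise RuntimeError(f"ephys stage failed: {exc}") from exc
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
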