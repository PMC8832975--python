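"""Pedigree model and PED-file input/output.

A pedigree is a directed acyclic graph of family members, each with sex,
affection status, and a flag recording whether an exome is available
("sequenced"). Only sequenced members take part in genotype-based filters;
deceased or unsampled members shape Mendelian transmission but are never
required to carry or lack a variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional

__all__ = ["Member", "PedigreeSpec", "read_ped", "write_ped"]

_SEXES = ("male", "female")
_AFFECTED = ("yes", "no", "unknown")


@dataclass(frozen=True)
class Member:
    """One individual in a pedigree."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "male"
    affected: str = "unknown"
    sequenced: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("member id must be non-empty")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.affected not in _AFFECTED:
            raise ValueError(
                f"affected must be one of {_AFFECTED}, got {self.affected!r}"
            )


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class PedigreeSpec:
    """A validated family structure.

    Validation enforces unique member ids, parent references that resolve
    within the pedigree, sex-consistent parents, and acyclicity.
    """

    members: list[Member]
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate member ids: {dupes}")
        by_id = {m.id: m for m in self.members}
        for m in self.members:
            for pid, want_sex in ((m.father_id, "male"), (m.mother_id, "female")):
                if pid is None:
                    continue
                if pid not in by_id:
                    raise PedigreeError(
                        f"member {m.id!r} references unknown parent {pid!r}"
                    )
                if by_id[pid].sex != want_sex:
                    raise PedigreeError(
                        f"parent {pid!r} of {m.id!r} has sex "
                        f"{by_id[pid].sex!r}, expected {want_sex!r}"
                    )
        self._by_id = by_id
        self._depths = self._compute_depths()

    # -- structure ---------------------------------------------------------

    def _compute_depths(self) -> dict[str, int]:
        """Generation depth per member; raises on ancestry cycles."""
        depths: dict[str, int] = {}
        DOING = object()
        state: dict[str, object] = {}

        def depth(mid: str) -> int:
            if mid in depths:
                return depths[mid]
            if state.get(mid) is DOING:
                raise PedigreeError(f"pedigree cycle involving {mid!r}")
            state[mid] = DOING
            m = self._by_id[mid]
            d = 0
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    d = max(d, depth(pid) + 1)
            depths[mid] = d
            state[mid] = None
            return d

        for m in self.members:
            depth(m.id)
        return depths

    def member(self, mid: str) -> Member:
        try:
            return self._by_id[mid]
        except KeyError:
            raise KeyError(f"no member {mid!r} in pedigree {self.family_id}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def __contains__(self, mid: str) -> bool:
        return mid in self._by_id

    def topological_order(self) -> list[Member]:
        """Members ordered so every parent precedes its children."""
        return sorted(self.members, key=lambda m: (self._depths[m.id], m.id))

    def founders(self) -> list[Member]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    @property
    def sequenced_ids(self) -> list[str]:
        return [m.id for m in self.members if m.sequenced]

    @property
    def affected_sequenced(self) -> list[str]:
        return [m.id for m in self.members if m.sequenced and m.affected == "yes"]

    @property
    def unaffected_sequenced(self) -> list[str]:
        return [m.id for m in self.members if m.sequenced and m.affected == "no"]

    def with_sequenced(self, sequenced_ids: Iterable[str]) -> "PedigreeSpec":
        """Copy of the pedigree with the sequenced flag set from a sample list."""
        seq = set(sequenced_ids)
        unknown = sorted(seq - set(self.ids))
        if unknown:
            raise PedigreeError(f"sequenced ids not in pedigree: {unknown}")
        return PedigreeSpec(
            [replace(m, sequenced=m.id in seq) for m in self.members],
            family_id=self.family_id,
        )

    # -- expected relatedness ---------------------------------------------

    def expected_kinship(self, a: str, b: str) -> float:
        """Pedigree-expected kinship coefficient phi.

        Classic recursive definition: phi(i,i) = 1/2 (1 + phi(father, mother)),
        and for distinct individuals the deeper one is expanded through its
        parents. Members with a missing parent are treated as outbred founders
        on that side.
        """
        self.member(a), self.member(b)

        @lru_cache(maxsize=None)
        def phi(i: Optional[str], j: Optional[str]) -> float:
            if i is None or j is None:
                return 0.0
            if i == j:
                m = self._by_id[i]
                return 0.5 * (1.0 + phi(m.father_id, m.mother_id))
            # expand the deeper member through its parents
            if self._depths[i] < self._depths[j]:
                i, j = j, i
            m = self._by_id[i]
            if m.father_id is None and m.mother_id is None:
                return 0.0
            return 0.5 * (phi(m.father_id, j) + phi(m.mother_id, j))

        return phi(a, b)


# -- PED dialect -----------------------------------------------------------

_SEX_TO_PED = {"male": "1", "female": "2"}
_PED_TO_SEX = {"1": "male", "2": "female"}
_AFF_TO_PED = {"no": "1", "yes": "2", "unknown": "0"}
_PED_TO_AFF = {"1": "no", "2": "yes", "0": "unknown", "-9": "unknown"}


def write_ped(ped: PedigreeSpec, path: str | Path) -> Path:
    """Write a 6-column PED file (FID IID father mother sex phenotype)."""
    path = Path(path)
    lines = []
    for m in ped.members:
        lines.append(
            "\t".join(
                [
                    ped.family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_TO_PED[m.sex],
                    _AFF_TO_PED[m.affected],
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ped(path: str | Path, sequenced_ids: Iterable[str] | None = None) -> PedigreeSpec:
    """Read a 6-column PED file (tab- or space-separated).

    ``sequenced_ids`` marks which members have genotype data (typically the
    VCF sample list); omitted, no member is flagged sequenced.
    """
    path = Path(path)
    members: list[Member] = []
    family_id = "FAM1"
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}"
            )
        fid, iid, fa, mo, sex, pheno = fields[:6]
        family_id = fid
        if sex not in _PED_TO_SEX:
            raise PedigreeError(f"{path}:{lineno}: unknown sex code {sex!r}")
        members.append(
            Member(
                id=iid,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=_PED_TO_SEX[sex],
                affected=_PED_TO_AFF.get(pheno, "unknown"),
            )
        )
    ped = PedigreeSpec(members, family_id=family_id)
    if sequenced_ids is not None:
        ped = ped.with_sequenced(sequenced_ids)
    return ped
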