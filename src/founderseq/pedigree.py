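"""Pedigree representation, PED/FAM parsing, and kinship computation.

A pedigree is a directed acyclic family graph: each individual either has
both parents recorded (a non-founder) or neither (a founder — original
colonists and married-in spouses alike).  The kinship coefficient
``phi[i, j]`` is the probability that one allele drawn at random from *i*
and one from *j* are identical by descent; the inbreeding coefficient of an
individual is the kinship of its parents, recoverable from the diagonal as
``h = 2 * phi[i, i] - 1``.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SEX_VALUES = ("male", "female", "unknown")
AFFECTION_VALUES = ("affected", "unaffected", "unknown")

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFFECTION_FROM_PED = {"1": "unaffected", "2": "affected"}
_AFFECTION_TO_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or malformed PED files."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both set or both ``None``;
    an individual with neither is a founder.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    genotyped: bool = False

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: father and mother must both be "
                f"specified or both be missing"
            )
        if self.sex not in SEX_VALUES:
            raise PedigreeError(f"individual {self.id!r}: invalid sex {self.sex!r}")
        if self.affection not in AFFECTION_VALUES:
            raise PedigreeError(
                f"individual {self.id!r}: invalid affection {self.affection!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """An ordered, validated collection of individuals forming one family graph."""

    individuals: list[IndividualRecord]
    family_id: str = "FAM1"
    _by_id: dict[str, IndividualRecord] = field(init=False, repr=False)
    _topo_order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        self._validate_parents()
        self._topo_order = self._topological_order()
        self._validate_sexes()

    # -- validation ---------------------------------------------------------

    def _validate_parents(self) -> None:
        for ind in self.individuals:
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown {role} {pid!r}"
                    )

    def _topological_order(self) -> list[str]:
        # parents before children; ties broken by input order
        order_index = {ind.id: k for k, ind in enumerate(self.individuals)}
        sorter: graphlib.TopologicalSorter[str] = graphlib.TopologicalSorter()
        for ind in self.individuals:
            preds = [p for p in (ind.father_id, ind.mother_id) if p is not None]
            sorter.add(ind.id, *preds)
        try:
            sorter.prepare()
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise PedigreeError(
                f"pedigree contains a parental cycle: {' -> '.join(cycle)}"
            ) from exc
        out: list[str] = []
        while sorter.is_active():
            ready = sorted(sorter.get_ready(), key=order_index.__getitem__)
            out.extend(ready)
            sorter.done(*ready)
        return out

    def _validate_sexes(self) -> None:
        fathers = {i.father_id for i in self.individuals if i.father_id is not None}
        mothers = {i.mother_id for i in self.individuals if i.mother_id is not None}
        fixed: dict[str, IndividualRecord] = {}
        for pid in fathers:
            rec = self._by_id[pid]
            if rec.sex == "female":
                raise PedigreeError(f"individual {pid!r} is female but listed as father")
            if rec.sex == "unknown":
                logger.warning("assigning sex 'male' to %r by paternal role", pid)
                fixed[pid] = replace(rec, sex="male")
        for pid in mothers:
            rec = self._by_id[pid]
            if rec.sex == "male":
                raise PedigreeError(f"individual {pid!r} is male but listed as mother")
            if rec.sex == "unknown":
                logger.warning("assigning sex 'female' to %r by maternal role", pid)
                fixed[pid] = replace(rec, sex="female")
        if fixed:
            self.individuals = [fixed.get(i.id, i) for i in self.individuals]
            self._by_id.update(fixed)

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, item: str) -> bool:
        return item in self._by_id

    def __getitem__(self, item: str) -> IndividualRecord:
        return self._by_id[item]

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    @property
    def founders(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.is_founder]

    @property
    def nonfounders(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if not i.is_founder]

    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        return list(self._topo_order)

    def children_of(self, parent_id: str) -> list[str]:
        return [
            i.id
            for i in self.individuals
            if parent_id in (i.father_id, i.mother_id)
        ]

    def leaves(self) -> list[str]:
        """Ids of individuals that are nobody's parent (the latest generation)."""
        parents = set()
        for ind in self.individuals:
            if ind.father_id is not None:
                parents.add(ind.father_id)
                parents.add(ind.mother_id)
        return [i.id for i in self.individuals if i.id not in parents]

    def generation_depth(self) -> dict[str, int]:
        """0 for founders; 1 + max(parent depth) otherwise."""
        depth: dict[str, int] = {}
        for iid in self._topo_order:
            ind = self._by_id[iid]
            if ind.is_founder:
                depth[iid] = 0
            else:
                depth[iid] = 1 + max(depth[ind.father_id], depth[ind.mother_id])
        return depth

    def n_generations(self) -> int:
        return max(self.generation_depth().values()) + 1 if self.individuals else 0


def pedigree_bits(pedigree: Pedigree | tuple[int, int]) -> int:
    """Pedigree complexity in bits: 2 * (#non-founders) - (#founders).

    The bit count governs the feasibility of exact multipoint likelihood
    methods on a pedigree.  Accepts either a ``Pedigree`` or a
    ``(n_nonfounders, n_founders)`` tuple of counts.
    """
    if isinstance(pedigree, Pedigree):
        n_non = len(pedigree.nonfounders)
        n_fou = len(pedigree.founders)
    else:
        n_non, n_fou = pedigree
    return 2 * n_non - n_fou


# ---------------------------------------------------------------------------
# PED / FAM input and output (PLINK dialect)
# ---------------------------------------------------------------------------

def parse_ped(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited PED/FAM file into a validated Pedigree.

    Columns: family, individual, father, mother, sex, phenotype; ``0``
    denotes a missing parent, unknown sex, or unknown phenotype
    (``-9`` is also accepted for phenotype).  Extra columns are ignored.
    """
    path = Path(path)
    individuals: list[IndividualRecord] = []
    seen: set[str] = set()
    family_ids: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected at least 6 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex, pheno = fields[:6]
            if iid in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual id {iid!r}")
            seen.add(iid)
            if fam not in family_ids:
                family_ids.append(fam)
            individuals.append(
                IndividualRecord(
                    id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_FROM_PED.get(sex, "unknown"),
                    affection=_AFFECTION_FROM_PED.get(pheno, "unknown"),
                )
            )
    family_id = family_ids[0] if len(family_ids) == 1 else ",".join(family_ids)
    return Pedigree(individuals=individuals, family_id=family_id)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    """Write a Pedigree as a 6-column tab-delimited PED/FAM file."""
    path = Path(path)
    with path.open("w") as fh:
        for ind in pedigree.individuals:
            fh.write(
                "\t".join(
                    [
                        pedigree.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_PED[ind.sex],
                        _AFFECTION_TO_PED[ind.affection],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients with the inbreeding vector.

    ``phi`` is symmetric with ``phi[i, i] = (1 + h_i) / 2`` where ``h_i`` is
    the inbreeding coefficient of individual *i* (the kinship of its
    parents); founders and other non-inbred individuals have
    ``phi[i, i] = 1/2``.
    """

    ids: list[str]
    phi: np.ndarray
    h: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.phi[self._index[id_a], self._index[id_b]])

    def inbreeding(self, iid: str) -> float:
        return float(self.h[self._index[iid]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self._index[i] for i in ids])
        return self.phi[np.ix_(idx, idx)]

    def cross_matrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri = np.array([self._index[i] for i in rows])
        ci = np.array([self._index[i] for i in cols])
        return self.phi[np.ix_(ri, ci)]

    def correlation_structure(self, ids: Sequence[str]) -> np.ndarray:
        """Genotype correlation matrix K: diag 1 + h_i, off-diagonal 2 phi_ij.

        Under Mendelian transmission the allele half-count of individual *i*
        has variance proportional to 1 + h_i and covariance proportional to
        2 phi_ij, which is the structure the quasi-likelihood association
        test corrects for.
        """
        sub = 2.0 * self.submatrix(ids)
        return sub  # diag = 2*phi_ii = 1 + h_i already


def kinship_matrix(pedigree: Pedigree) -> KinshipMatrix:
    """Recursive kinship over the whole pedigree.

    Individuals are processed ancestors-first.  Founders get
    ``phi[i, i] = 1/2`` and zero kinship with everyone already processed;
    a non-founder *i* with parents (f, m) gets
    ``phi[i, i] = (1 + phi[f, m]) / 2`` and
    ``phi[i, j] = (phi[f, j] + phi[m, j]) / 2`` for every earlier *j*.
    Returned in the pedigree's input order.
    """
    order = pedigree.topological_order()
    n = len(order)
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        ind = pedigree[iid]
        if ind.is_founder:
            phi[k, k] = 0.5
            # phi[k, j] stays 0 for all j processed earlier
        else:
            f, m = pos[ind.father_id], pos[ind.mother_id]
            phi[k, k] = 0.5 * (1.0 + phi[f, m])
            phi[k, :k] = 0.5 * (phi[f, :k] + phi[m, :k])
            phi[:k, k] = phi[k, :k]
    # permute back to input order
    perm = np.array([pos[iid] for iid in pedigree.ids])
    phi = phi[np.ix_(perm, perm)]
    h = 2.0 * np.diag(phi) - 1.0
    return KinshipMatrix(ids=pedigree.ids, phi=phi, h=h)
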