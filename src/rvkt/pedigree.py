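"""Pedigree parsing, validation, and exact kinship coefficients.

A pedigree is a DAG of individuals with parent links.  The kinship
coefficient phi(i, j) is the probability that one allele drawn at random
from i and one from j at an autosomal locus are identical by descent
through the recorded pedigree.  Founders (both parents unrecorded) are
assumed unrelated and non-inbred, so phi(i, i) = 1/2 for a founder and
phi(i, j) = 0 between founders.

Kinship is computed by the standard tabular recursion in topological
order (parents before offspring), which is exact for arbitrary inbred
pedigrees: for a non-founder i with parents f and m and any j ordered
before i, phi(i, j) = (phi(f, j) + phi(m, j)) / 2, and
phi(i, i) = (1 + phi(f, m)) / 2.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "with_study_subjects",
    "KinshipMatrix",
    "PedigreeError",
    "DuplicateIndividualError",
    "MissingParentError",
    "SingleParentError",
    "PedigreeCycleError",
    "read_ped",
    "compute_kinship",
    "mean_pairwise_kinship",
    "classify_pairs",
    "RELATIONSHIP_CATEGORIES",
]

MISSING_PARENT = "0"

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIndividualError(PedigreeError):
    """The same individual id appears more than once."""


class MissingParentError(PedigreeError):
    """A parent id is referenced but no such individual exists."""


class SingleParentError(PedigreeError):
    """Exactly one parent is recorded; individuals are founders or have both."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders.  ``sex`` is
    stored as read ("male"/"female"/"unknown") but never enters any
    computation: kinship here is autosomal.  ``is_study_subject``
    separates phenotyped subjects from relatives that only connect them.
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    is_study_subject: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated collection of individuals with a topological order.

    Individuals are keyed by individual id, which must be unique across
    the whole input (families are disjoint components; cross-family
    parent references are rejected).
    """

    def __init__(self, members: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.individual_id in self._members:
                raise DuplicateIndividualError(
                    f"duplicate individual id {ind.individual_id!r}"
                )
            self._members[ind.individual_id] = ind
        self._validate()
        self._order = self._topological_order()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    def __iter__(self):
        return iter(self._members.values())

    @property
    def members(self) -> list[Individual]:
        return list(self._members.values())

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self if ind.is_founder]

    @property
    def study_subject_ids(self) -> list[str]:
        return [ind.individual_id for ind in self if ind.is_study_subject]

    @property
    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its offspring."""
        return list(self._order)

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for ind in self:
            has_f = ind.father_id is not None
            has_m = ind.mother_id is not None
            if has_f != has_m:
                raise SingleParentError(
                    f"individual {ind.individual_id!r} has exactly one recorded "
                    "parent; founders must have both parents missing"
                )
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise MissingParentError(
                        f"individual {ind.individual_id!r} references parent "
                        f"{pid!r} which is not in the pedigree"
                    )
                if self._members[pid].family_id != ind.family_id:
                    raise MissingParentError(
                        f"individual {ind.individual_id!r} (family "
                        f"{ind.family_id!r}) references parent {pid!r} from a "
                        "different family; families must be self-contained"
                    )

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm over parent -> child edges; leftover nodes mean
        # someone is their own ancestor.
        children: dict[str, list[str]] = {iid: [] for iid in self._members}
        n_parents: dict[str, int] = {}
        for ind in self:
            parents = [] if ind.is_founder else [ind.father_id, ind.mother_id]
            n_parents[ind.individual_id] = len(parents)
            for pid in parents:
                children[pid].append(ind.individual_id)
        ready = deque(iid for iid, k in n_parents.items() if k == 0)
        order: list[str] = []
        while ready:
            iid = ready.popleft()
            order.append(iid)
            for child in children[iid]:
                n_parents[child] -= 1
                if n_parents[child] == 0:
                    ready.append(child)
        if len(order) != len(self._members):
            stuck = sorted(set(self._members) - set(order))
            raise PedigreeCycleError(
                f"pedigree contains a cycle involving individuals {stuck}"
            )
        return order

    # -- convenience --------------------------------------------------------
    def parent_indices(self, order: Sequence[str] | None = None):
        """Father/mother positions of each individual within ``order``.

        Returns ``(fathers, mothers)`` int arrays aligned to ``order``
        (default: the topological order); founders get -1.  Used by the
        simulators to walk the pedigree with vectorized numpy ops.
        """
        order = list(order) if order is not None else self.topological_order
        pos = {iid: k for k, iid in enumerate(order)}
        fa = np.full(len(order), -1, dtype=np.int64)
        mo = np.full(len(order), -1, dtype=np.int64)
        for k, iid in enumerate(order):
            ind = self._members[iid]
            if not ind.is_founder:
                fa[k] = pos[ind.father_id]
                mo[k] = pos[ind.mother_id]
        return fa, mo


def with_study_subjects(ped: Pedigree, study_ids: Iterable[str]) -> Pedigree:
    """Copy of ``ped`` with the study-subject flag set to ``study_ids``.

    Used to mark phenotyped individuals once a phenotype table is known;
    everyone else becomes a connecting relative.
    """
    wanted = set(study_ids)
    unknown = wanted - set(ped.ids)
    if unknown:
        raise KeyError(f"study ids not in pedigree: {sorted(unknown)[:5]}")
    return Pedigree(
        Individual(
            individual_id=ind.individual_id,
            family_id=ind.family_id,
            father_id=ind.father_id,
            mother_id=ind.mother_id,
            sex=ind.sex,
            is_study_subject=ind.individual_id in wanted,
        )
        for ind in ped
    )


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise kinship coefficients.

    ``phi[i, i]`` is the self-kinship (1 + F_i) / 2 where F_i is the
    inbreeding coefficient of i.
    """

    ids: list[str]
    phi: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match ids")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in kinship matrix") from None

    def get(self, id1: str, id2: str) -> float:
        return float(self.phi[self._index[id1], self._index[id2]])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = self.indices(ids)
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)])

    def inbreeding(self, iid: str) -> float:
        """Inbreeding coefficient F = 2*phi_ii - 1."""
        k = self._index[iid]
        return float(2.0 * self.phi[k, k] - 1.0)

    # -- writers ------------------------------------------------------------
    def to_long_frame(self, include_self: bool = False) -> pd.DataFrame:
        """Long format (id1, id2, phi) over unordered pairs i < j."""
        n = len(self.ids)
        iu = np.triu_indices(n, k=0 if include_self else 1)
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu[0]],
                "id2": [self.ids[j] for j in iu[1]],
                "phi": self.phi[iu],
            }
        )

    def write_long_tsv(self, path: str | Path, include_self: bool = False) -> None:
        self.to_long_frame(include_self).to_csv(path, sep="\t", index=False)

    def write_matrix_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )


# ---------------------------------------------------------------------------
# PED parsing / writing
# ---------------------------------------------------------------------------

def read_ped(
    path: str | Path | io.TextIOBase,
    dialect: str = "whitespace",
) -> Pedigree:
    """Read a PLINK-style PED/FAM file into a validated :class:`Pedigree`.

    Expected columns (at least 6): FID IID PAT MAT SEX PHENO, with "0"
    marking a missing parent.  The phenotype column is ignored here —
    phenotypes come from a separate table.  ``dialect`` is "whitespace"
    (any run of blanks) or "tab".
    """
    if dialect not in ("whitespace", "tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    members: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if dialect == "tab" else line.split()
        fields = [f.strip() for f in fields]
        if len(fields) < 6:
            raise PedigreeError(
                f"line {lineno}: expected at least 6 columns "
                f"(FID IID PAT MAT SEX PHENO), got {len(fields)}"
            )
        fid, iid, pat, mat, sex = fields[:5]
        if (fid, iid) in seen:
            raise DuplicateIndividualError(
                f"line {lineno}: duplicate individual {iid!r} in family {fid!r}"
            )
        seen.add((fid, iid))
        members.append(
            Individual(
                individual_id=iid,
                family_id=fid,
                father_id=None if pat == MISSING_PARENT else pat,
                mother_id=None if mat == MISSING_PARENT else mat,
                sex=SEX_CODES.get(sex, "unknown"),
            )
        )
    return Pedigree(members)


def write_ped(ped: Pedigree, path: str | Path, header: str | None = None) -> None:
    """Write a Pedigree as tab-delimited PED (phenotype column written as 0)."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for iid in ped.topological_order:
            ind = ped[iid]
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or MISSING_PARENT,
                        ind.mother_id or MISSING_PARENT,
                        sex_out[ind.sex],
                        "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Exact kinship coefficients for every pair of pedigree members.

    Tabular recursion in topological order; O(n^2) time, deterministic.
    The returned matrix is ordered by the pedigree's input id order.
    """
    order = ped.topological_order
    n = len(order)
    fa, mo = ped.parent_indices(order)
    phi = np.zeros((n, n))
    for k in range(n):
        if fa[k] < 0:  # founder: unrelated to all predecessors, F = 0
            phi[k, k] = 0.5
            continue
        f, m = fa[k], mo[k]
        row = 0.5 * (phi[f, :k] + phi[m, :k])
        phi[k, :k] = row
        phi[:k, k] = row
        phi[k, k] = 0.5 * (1.0 + phi[f, m])
    # restore the caller-facing id order
    want = ped.ids
    pos = {iid: i for i, iid in enumerate(order)}
    perm = np.array([pos[iid] for iid in want], dtype=np.int64)
    return KinshipMatrix(want, phi[np.ix_(perm, perm)])


def mean_pairwise_kinship(K: KinshipMatrix, subset: Sequence[str]) -> float:
    """Mean of phi(i, j) over all unordered pairs in ``subset``.

    Self-kinship is excluded.  This is the test statistic: large values
    mean the subset is more closely related than a random draw.
    """
    if len(subset) < 2:
        raise ValueError("mean pairwise kinship requires at least 2 individuals")
    idx = K.indices(subset)
    if len(set(idx.tolist())) != len(idx):
        raise ValueError("subset contains repeated ids")
    sub = K.phi[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


# ---------------------------------------------------------------------------
# Relationship classification
# ---------------------------------------------------------------------------

RELATIONSHIP_CATEGORIES = [
    "parent-offspring",
    "siblings",
    "grandparent-grandchild",
    "avuncular",
    "1st cousins",
    "1st cousins once removed",
    "2nd cousins",
    "other",
]


def _parents(ped: Pedigree, iid: str) -> tuple[str, ...]:
    ind = ped[iid]
    return () if ind.is_founder else (ind.father_id, ind.mother_id)


def _full_sibs(ped: Pedigree, a: str, b: str) -> bool:
    pa, pb = _parents(ped, a), _parents(ped, b)
    return bool(pa) and set(pa) == set(pb) and a != b


def _classify_one(ped: Pedigree, a: str, b: str) -> str:
    """Assign one related pair to a category by explicit pedigree paths.

    Structural tests (shared parents, generation offsets) rather than
    kinship-value thresholds, so inbreeding cannot miscategorize a pair.
    Checks run from closest to most distant; the first match wins.
    """
    pa, pb = _parents(ped, a), _parents(ped, b)
    if a in pb or b in pa:
        return "parent-offspring"
    if _full_sibs(ped, a, b):
        return "siblings"
    grand_a = {g for p in pa for g in _parents(ped, p)}
    grand_b = {g for p in pb for g in _parents(ped, p)}
    if a in grand_b or b in grand_a:
        return "grandparent-grandchild"
    # avuncular: one individual is a full sibling of the other's parent
    if any(_full_sibs(ped, a, p) for p in pb) or any(
        _full_sibs(ped, b, p) for p in pa
    ):
        return "avuncular"
    if any(_full_sibs(ped, x, y) for x in pa for y in pb):
        return "1st cousins"
    # once removed: a is first cousin of one of b's parents, or vice versa
    def first_cousins(x: str, y: str) -> bool:
        return any(
            _full_sibs(ped, u, v) for u in _parents(ped, x) for v in _parents(ped, y)
        )

    if any(first_cousins(a, p) for p in pb) or any(first_cousins(b, p) for p in pa):
        return "1st cousins once removed"
    if any(first_cousins(x, y) for x in pa for y in pb):
        return "2nd cousins"
    return "other"


def classify_pairs(ped: Pedigree, K: KinshipMatrix) -> pd.DataFrame:
    """Count study-subject pairs with phi > 0 by relationship category.

    Returns a DataFrame indexed by category with an ``n_pairs`` column;
    unrelated pairs (phi == 0) are excluded.
    """
    subjects = ped.study_subject_ids
    idx = K.indices(subjects)
    counts = dict.fromkeys(RELATIONSHIP_CATEGORIES, 0)
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            if K.phi[idx[i], idx[j]] > 0.0:
                counts[_classify_one(ped, subjects[i], subjects[j])] += 1
    return pd.DataFrame(
        {"n_pairs": [counts[c] for c in RELATIONSHIP_CATEGORIES]},
        index=pd.Index(RELATIONSHIP_CATEGORIES, name="relationship"),
    )
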