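"""Quantitative-trait simulation on pedigrees.

Two ingredients, both conditional on the observed pedigree:

* a purely polygenic (infinitesimal) trait — the null model: additive
  genetic values propagated by Mendelian sampling down the pedigree,
  plus independent environmental noise, with total variance 1;
* a rare biallelic variant gene-dropped from the founders, whose
  additive effect is sized to explain a chosen fraction of the total
  trait variance — the alternative model adds this on top of a reduced
  polygenic background.

Mendelian sampling is exact for inbred pedigrees: an offspring's
additive value is the parental midvalue plus a deviation with variance
(h2/2) * (1 - (F_f + F_m)/2), where F is a parent's inbreeding
coefficient.  In expectation the additive values have covariance
2 * Phi * h2, the infinitesimal-model form.

All simulators are vectorized over replicates: one generator stream per
call, individuals visited in topological order, replicates as columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, KinshipMatrix, Pedigree, compute_kinship, write_ped

__all__ = [
    "RareVariantSpec",
    "TraitModel",
    "SimulatedTrait",
    "simulate_polygenic",
    "drop_rare_variant",
    "simulate_trait",
    "make_nuclear_families",
    "make_sibpair_families",
    "write_cohort",
]


@dataclass(frozen=True)
class RareVariantSpec:
    """A single additive biallelic locus with a rare trait-influencing allele.

    Parameters
    ----------
    q
        Founder frequency of the trait-influencing allele (Hardy-Weinberg
        proportions among founders; typical screening range (0, 0.05]).
    v
        Fraction of the TOTAL trait variance the locus explains in a
        random-mating population: v = 2 q (1-q) a^2 for per-allele
        effect a.  Give either ``v`` or ``v_genetic`` (fraction of the
        genetic variance, converted as v = v_genetic * h2 at use time).
    direction
        "raise" (allele increases the trait) or "lower".
    """

    q: float
    v: float | None = None
    v_genetic: float | None = None
    direction: Literal["raise", "lower"] = "raise"

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"allele frequency q must be in (0, 1), got {self.q}")
        if (self.v is None) == (self.v_genetic is None):
            raise ValueError("give exactly one of v (total) or v_genetic")
        if self.direction not in ("raise", "lower"):
            raise ValueError(f"direction must be 'raise' or 'lower', got {self.direction!r}")
        vv = self.v if self.v is not None else self.v_genetic
        if not 0.0 < vv < 1.0:
            raise ValueError(f"variance fraction must be in (0, 1), got {vv}")

    def variance_fraction(self, h2: float) -> float:
        """Fraction of total trait variance, resolving v_genetic if given."""
        return self.v if self.v is not None else self.v_genetic * h2

    def allele_effect(self, h2: float) -> float:
        """Per-allele additive effect a = sqrt(v / (2 q (1-q)))."""
        v = self.variance_fraction(h2)
        return float(np.sqrt(v / (2.0 * self.q * (1.0 - self.q))))

    @property
    def carrier_frequency(self) -> float:
        """Expected fraction carrying >= 1 allele: 2q(1-q) + q^2."""
        return 2.0 * self.q * (1.0 - self.q) + self.q**2


@dataclass(frozen=True)
class TraitModel:
    """Generative model for one simulated trait (total variance 1).

    ``h2`` is the narrow-sense heritability; if ``rare_variant`` is set
    its variance fraction v must satisfy 0 < v <= h2 (the variant is one
    of the additive genetic factors), leaving h2 - v of polygenic
    background.
    """

    h2: float
    rare_variant: RareVariantSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        if self.rare_variant is not None:
            v = self.rare_variant.variance_fraction(self.h2)
            if not 0.0 < v <= self.h2:
                raise ValueError(
                    "rare variant cannot exceed genetic variance: "
                    f"v={v:.4g} > h2={self.h2:.4g}"
                )


@dataclass
class SimulatedTrait:
    """Simulated trait values for the pedigree's study subjects.

    ``values``: DataFrame indexed by individual id with one column per
    replicate.  ``carrier_status``: matching frame of rare-allele copy
    counts (0/1/2), or None under the null model.
    """

    values: pd.DataFrame
    carrier_status: pd.DataFrame | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Core vectorized machinery (individuals x replicates arrays, topo order)
# ---------------------------------------------------------------------------

def _pedigree_walk(ped: Pedigree, K: KinshipMatrix | None):
    """Topological order, parent indices, and per-parent inbreeding terms."""
    order = ped.topological_order
    fa, mo = ped.parent_indices(order)
    if K is None:
        K = compute_kinship(ped)
    F = np.array([K.inbreeding(iid) for iid in order])
    return order, fa, mo, F


def _additive_values(
    ped: Pedigree,
    K: KinshipMatrix | None,
    var_a: float,
    rng: np.random.Generator,
    n_replicates: int,
):
    """Additive genetic values with variance ``var_a``, Mendelian sampling.

    Returns (order, values) with values shaped (n_members, n_replicates).
    """
    order, fa, mo, F = _pedigree_walk(ped, K)
    n = len(order)
    a = np.empty((n, n_replicates))
    z = rng.standard_normal((n, n_replicates))
    founder = fa < 0
    a[founder] = np.sqrt(var_a) * z[founder]
    for k in np.flatnonzero(~founder):
        f, m = fa[k], mo[k]
        mend_var = 0.5 * var_a * (1.0 - 0.5 * (F[f] + F[m]))
        a[k] = 0.5 * (a[f] + a[m]) + np.sqrt(mend_var) * z[k]
    return order, a


def _gene_drop(
    ped: Pedigree,
    q: float,
    rng: np.random.Generator,
    n_replicates: int,
):
    """Drop a biallelic variant down the pedigree.

    Founders get two alleles iid Bernoulli(q); each offspring inherits
    one uniformly chosen allele from each parent.  Returns (order,
    copies) with copies in {0, 1, 2}, shape (n_members, n_replicates).
    """
    order = ped.topological_order
    fa, mo = ped.parent_indices(order)
    n = len(order)
    a1 = np.zeros((n, n_replicates), dtype=np.int8)
    a2 = np.zeros((n, n_replicates), dtype=np.int8)
    founder = fa < 0
    n_founders = int(founder.sum())
    a1[founder] = rng.random((n_founders, n_replicates)) < q
    a2[founder] = rng.random((n_founders, n_replicates)) < q
    for k in np.flatnonzero(~founder):
        f, m = fa[k], mo[k]
        pick_f = rng.random(n_replicates) < 0.5
        pick_m = rng.random(n_replicates) < 0.5
        a1[k] = np.where(pick_f, a1[f], a2[f])
        a2[k] = np.where(pick_m, a1[m], a2[m])
    return order, (a1 + a2)


def _subjects_frame(ped: Pedigree, order: list[str], mat: np.ndarray) -> pd.DataFrame:
    """Restrict a members x replicates array to study subjects."""
    pos = {iid: k for k, iid in enumerate(order)}
    ids = ped.study_subject_ids
    rows = np.array([pos[i] for i in ids], dtype=np.int64)
    return pd.DataFrame(mat[rows], index=pd.Index(ids, name="id"))


# ---------------------------------------------------------------------------
# Public simulators
# ---------------------------------------------------------------------------

def simulate_polygenic(
    ped: Pedigree,
    K: KinshipMatrix | None,
    h2: float,
    seed: int | np.random.Generator,
    n_replicates: int = 1,
) -> SimulatedTrait:
    """Simulate a purely polygenic trait (the null model), total variance 1.

    trait = additive genetic value (variance h2, covariance 2*Phi*h2
    across relatives) + independent environment (variance 1 - h2).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 must be in [0, 1), got {h2}")
    rng = np.random.default_rng(seed)
    order, a = _additive_values(ped, K, h2, rng, n_replicates)
    y = a + np.sqrt(1.0 - h2) * rng.standard_normal(a.shape)
    return SimulatedTrait(values=_subjects_frame(ped, order, y))


def drop_rare_variant(
    ped: Pedigree,
    q: float,
    seed: int | np.random.Generator,
    n_replicates: int = 1,
    study_subjects_only: bool = True,
) -> pd.DataFrame:
    """Gene-drop a biallelic allele at founder frequency q; copy counts 0/1/2.

    Replicates with zero carriers are legitimate draws (no conditioning
    on the variant segregating).  q = 0 or 1 are allowed degenerate
    inputs (all-0 / all-2).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    rng = np.random.default_rng(seed)
    order, copies = _gene_drop(ped, q, rng, n_replicates)
    if study_subjects_only:
        return _subjects_frame(ped, order, copies)
    return pd.DataFrame(copies, index=pd.Index(order, name="id"))


def simulate_trait(
    ped: Pedigree,
    K: KinshipMatrix | None,
    model: TraitModel,
    n_replicates: int = 1,
    seed: int | np.random.Generator | None = None,
) -> SimulatedTrait:
    """Simulate a trait under ``model`` (null or rare-variant alternative).

    With a rare variant of variance fraction v and per-allele effect a:
    trait = +/- a * (copies - 2q)  (mean-centered variant term)
            + polygenic background with variance h2 - v
            + environment with variance 1 - h2.
    Without one, identical in distribution to :func:`simulate_polygenic`.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    rv = model.rare_variant
    if rv is None:
        return simulate_polygenic(ped, K, model.h2, rng, n_replicates)
    v = rv.variance_fraction(model.h2)
    a_eff = rv.allele_effect(model.h2)
    sign = 1.0 if rv.direction == "raise" else -1.0
    order, copies = _gene_drop(ped, rv.q, rng, n_replicates)
    _, poly = _additive_values(ped, K, model.h2 - v, rng, n_replicates)
    env = np.sqrt(1.0 - model.h2) * rng.standard_normal(poly.shape)
    y = sign * a_eff * (copies - 2.0 * rv.q) + poly + env
    return SimulatedTrait(
        values=_subjects_frame(ped, order, y),
        carrier_status=_subjects_frame(ped, order, copies).astype(int),
    )


# ---------------------------------------------------------------------------
# Synthetic cohort generators
# ---------------------------------------------------------------------------

def make_nuclear_families(n_families: int) -> Pedigree:
    """``n_families`` disjoint four-person nuclear families.

    Two founder parents and two full-sib offspring per family, all four
    study subjects.  Deterministic ids: family Fk, members Fk_P1 (father),
    Fk_P2 (mother), Fk_C1, Fk_C2.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    members: list[Individual] = []
    for k in range(1, n_families + 1):
        fid = f"F{k:04d}"
        p1, p2 = f"{fid}_P1", f"{fid}_P2"
        members.append(Individual(p1, fid, sex="male"))
        members.append(Individual(p2, fid, sex="female"))
        for c in ("C1", "C2"):
            members.append(Individual(f"{fid}_{c}", fid, father_id=p1, mother_id=p2))
    return Pedigree(members)


def make_sibpair_families(n_families: int) -> Pedigree:
    """``n_families`` families of one full-sib pair each.

    The two parents are present as connecting relatives but are not
    study subjects, so the study sample is 2 * n_families siblings and
    the only nonzero study-subject kinship is 0.25 within a family.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    members: list[Individual] = []
    for k in range(1, n_families + 1):
        fid = f"S{k:04d}"
        p1, p2 = f"{fid}_P1", f"{fid}_P2"
        members.append(Individual(p1, fid, sex="male", is_study_subject=False))
        members.append(Individual(p2, fid, sex="female", is_study_subject=False))
        for c in ("C1", "C2"):
            members.append(Individual(f"{fid}_{c}", fid, father_id=p1, mother_id=p2))
    return Pedigree(members)


def write_cohort(
    ped: Pedigree,
    trait: SimulatedTrait,
    out_dir: str | Path,
    trait_names: Sequence[str] | None = None,
    header: str | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort: PED, phenotype TSV, and carrier TSV.

    Each trait column of ``trait.values`` becomes one phenotype column;
    carrier counts (if present) are written per (trait, individual).
    Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = (
        list(trait_names)
        if trait_names is not None
        else [f"trait_{j + 1}" for j in range(trait.values.shape[1])]
    )
    paths = {"ped": out_dir / "cohort.ped", "phenotypes": out_dir / "phenotypes.tsv"}
    write_ped(ped, paths["ped"], header=header)
    pheno = trait.values.copy()
    pheno.columns = names
    with open(paths["phenotypes"], "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pheno.to_csv(fh, sep="\t", index_label="id")
    if trait.carrier_status is not None:
        carriers = trait.carrier_status.copy()
        carriers.columns = names
        paths["carriers"] = out_dir / "carriers.tsv"
        with open(paths["carriers"], "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            carriers.to_csv(fh, sep="\t", index_label="id")
    return paths
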