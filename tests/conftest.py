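"""Shared pedigree fixtures, generated programmatically."""

import numpy as np
import pytest

from rvkt.pedigree import Individual, Pedigree, compute_kinship


def ped_from_rows(rows):
    """rows: (iid, fid, father, mother) with None for founders."""
    return Pedigree(
        Individual(iid, fid, father_id=fa, mother_id=mo) for iid, fid, fa, mo in rows
    )


@pytest.fixture(scope="session")
def three_generation_ped():
    """Grandparents -> two sibs (one married in) -> grandchildren + cousins."""
    rows = [
        ("gp1", "A", None, None), ("gp2", "A", None, None),
        ("p1", "A", "gp1", "gp2"), ("p2", "A", "gp1", "gp2"),  # full sibs
        ("s1", "A", None, None), ("s2", "A", None, None),      # spouses
        ("c1", "A", "p1", "s1"), ("c2", "A", "p1", "s1"),      # p1's children
        ("d1", "A", "p2", "s2"),                               # p2's child
    ]
    return ped_from_rows(rows)


@pytest.fixture(scope="session")
def halfsib_mating_ped():
    """Child of a half-sib mating: inbred, self-kinship (1 + 1/8) / 2."""
    rows = [
        ("a", "H", None, None), ("b", "H", None, None), ("c", "H", None, None),
        ("h1", "H", "a", "b"), ("h2", "H", "a", "c"),  # half sibs via father a
        ("x", "H", "h1", "h2"),
        ("y", "H", None, None),  # unrelated extra member
    ]
    return ped_from_rows(rows)


@pytest.fixture(scope="session")
def cousin_ped():
    """First cousins c1 x d1 (children of full sibs) plus second cousins."""
    rows = [
        ("g1", "C", None, None), ("g2", "C", None, None),
        ("u1", "C", "g1", "g2"), ("u2", "C", "g1", "g2"),
        ("w1", "C", None, None), ("w2", "C", None, None),
        ("c1", "C", "u1", "w1"), ("d1", "C", "u2", "w2"),       # 1st cousins
        ("w3", "C", None, None), ("w4", "C", None, None),
        ("e1", "C", "c1", "w3"), ("f1", "C", "d1", "w4"),       # 2nd cousins
    ]
    return ped_from_rows(rows)


@pytest.fixture(scope="session")
def kinship_cache():
    cache = {}

    def get(ped):
        key = id(ped)
        if key not in cache:
            cache[key] = compute_kinship(ped)
        return cache[key]

    return get


def gene_drop_ibd_oracle(ped, n_drops=100_000, seed=0):
    """Monte-Carlo kinship oracle: IBD frequency of randomly drawn alleles.

    Founders get globally unique allele labels; alleles are transmitted
    down the pedigree; phi_hat(i, j) is the average probability that one
    random allele of i matches one random allele of j by label.  Exact
    recursion must agree within Monte-Carlo error.  Returns (ids,
    phi_hat, mc_se) aligned to the pedigree id order.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order
    fa, mo = ped.parent_indices(order)
    n = len(order)
    a1 = np.zeros((n, n_drops), dtype=np.int32)
    a2 = np.zeros((n, n_drops), dtype=np.int32)
    label = 0
    for k in np.flatnonzero(fa < 0):
        a1[k] = 2 * label
        a2[k] = 2 * label + 1
        label += 1
    for k in np.flatnonzero(fa >= 0):
        f, m = fa[k], mo[k]
        a1[k] = np.where(rng.random(n_drops) < 0.5, a1[f], a2[f])
        a2[k] = np.where(rng.random(n_drops) < 0.5, a1[m], a2[m])
    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                # P(two alleles drawn with replacement from i are IBD)
                p = 0.5 * (1.0 + (a1[i] == a2[i]))
            else:
                p = 0.25 * (
                    (a1[i] == a1[j]).astype(float) + (a1[i] == a2[j])
                    + (a2[i] == a1[j]) + (a2[i] == a2[j])
                )
            phi_hat[i, j] = phi_hat[j, i] = p.mean()
            se[i, j] = se[j, i] = p.std(ddof=1) / np.sqrt(n_drops)
    pos = {iid: k for k, iid in enumerate(order)}
    perm = np.array([pos[i] for i in ped.ids])
    return ped.ids, phi_hat[np.ix_(perm, perm)], se[np.ix_(perm, perm)]
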