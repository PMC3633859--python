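"""The Rare Variant Kinship Test statistic, empirical null, and p-values.

The test statistic for one trait and one tail is the mean pairwise
kinship coefficient among the individuals in that tail of the trait
distribution.  Under the null hypothesis the trait is purely polygenic,
so tail members are no more related than a polygenic model predicts;
under the alternative, tail members preferentially share a rare variant
identical by descent and the statistic is inflated.  The null
distribution depends on the pedigrees and the trait's heritability and
has no convenient closed form, so it is generated by simulation: many
polygenic replicates on the observed pedigrees, each scored with the
same statistic.  The test is one-sided (excess relatedness only).

Because the statistic takes few distinct values on simple pedigrees, the
empirical CDF is discrete; rejection regions are chosen with size as
close to the nominal level as possible without exceeding it, and the
achieved size is always reported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix, Pedigree
from .simulate import simulate_polygenic

__all__ = [
    "TailSpec",
    "NullDistribution",
    "RvktResult",
    "RejectionRule",
    "DegenerateTraitWarning",
    "tail_count",
    "select_tail",
    "rvkt_statistic",
    "build_null",
    "empirical_pvalue",
    "format_pvalue",
    "min_p_over_tails",
    "rejection_threshold",
    "null_support_summary",
    "test_trait",
    "results_frame",
    "write_results",
]

# Tolerance for >=/equality comparisons between statistic values: the
# statistic lives on a coarse lattice (multiples of 0.25 / n_pairs on
# simple pedigrees), so ties must compare equal despite float summation
# order.
_STAT_ATOL = 1e-9
_STAT_DECIMALS = 9


class DegenerateTraitWarning(UserWarning):
    """Tail membership was decided by id order among tied trait values."""


@dataclass(frozen=True)
class TailSpec:
    """One tail of a trait distribution: side, fraction, resolved count."""

    side: Literal["lower", "upper"]
    fraction: float
    n_tail: int

    def __post_init__(self) -> None:
        if self.side not in ("lower", "upper"):
            raise ValueError(f"side must be 'lower' or 'upper', got {self.side!r}")
        if not 0.0 < self.fraction < 0.5:
            raise ValueError(f"tail fraction must be in (0, 0.5), got {self.fraction}")
        if self.n_tail < 2:
            raise ValueError(f"n_tail must be >= 2, got {self.n_tail}")

    @classmethod
    def resolve(
        cls, side: Literal["lower", "upper"], fraction: float, n_subjects: int
    ) -> "TailSpec":
        return cls(side=side, fraction=fraction, n_tail=tail_count(n_subjects, fraction))

    @property
    def label(self) -> str:
        return f"{self.side}:{self.fraction:g}"


def tail_count(n_subjects: int, fraction: float) -> int:
    """Resolve a tail fraction to a subject count: round-half-up of n * f.

    Round-half-up reproduces the canonical 1/2/4/6/8% tail counts of
    15/30/59/89/118 subjects at n = 1,481.  A resolved count below 2 is
    an error (the statistic needs at least one pair).
    """
    if n_subjects < 4:
        raise ValueError(f"need at least 4 subjects, got {n_subjects}")
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"tail fraction must be in (0, 0.5), got {fraction}")
    # nudge guards against 0.06*1481 = 88.8599...94 style representation
    n_tail = int(math.floor(n_subjects * fraction + 0.5 + 1e-9))
    if n_tail < 2:
        raise ValueError(
            f"tail of {fraction:g} on {n_subjects} subjects resolves to "
            f"{n_tail} < 2 individuals; the statistic is undefined"
        )
    return n_tail


def select_tail(trait: pd.Series, tail: TailSpec) -> list[str]:
    """Ids of the ``n_tail`` most extreme non-missing trait values.

    Ties at the tail boundary are broken deterministically by individual
    id (ascending); a tie that decides membership, or an all-constant
    trait, raises :class:`DegenerateTraitWarning`.
    """
    values = trait.dropna()
    if len(values) < tail.n_tail:
        raise ValueError(
            f"trait has {len(values)} non-missing values, fewer than the "
            f"tail count {tail.n_tail}"
        )
    ascending = tail.side == "lower"
    # stable sort on (value, id): id order breaks exact ties
    ordered = values.sort_index().sort_values(ascending=ascending, kind="stable")
    chosen = ordered.iloc[: tail.n_tail]
    boundary = chosen.iloc[-1]
    n_at_boundary = int((values == boundary).sum())
    n_chosen_at_boundary = int((chosen == boundary).sum())
    if n_at_boundary > n_chosen_at_boundary:
        warnings.warn(
            f"{n_at_boundary} subjects tie at the {tail.label} tail boundary "
            f"value {boundary!r}; membership resolved by id order",
            DegenerateTraitWarning,
            stacklevel=2,
        )
    return list(chosen.index)


def rvkt_statistic(trait: pd.Series, tail: TailSpec, K: KinshipMatrix) -> float:
    """Mean pairwise kinship among the tail members of ``trait``.

    Depends on trait values only through their ranks, so it is invariant
    under any strictly increasing transform of the trait.
    """
    from .pedigree import mean_pairwise_kinship

    return mean_pairwise_kinship(K, select_tail(trait, tail))


@dataclass
class NullDistribution:
    """Empirical null of the statistic for one tail under a polygenic trait."""

    tail: TailSpec
    h2: float
    values: np.ndarray
    seed: int
    n_subjects: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("null values must be a non-empty 1-d array")
        if (self.values < -_STAT_ATOL).any():
            raise ValueError("null statistic values must be non-negative")

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def ci95(self) -> tuple[float, float]:
        """Approximate 95% interval: 2.5th-97.5th percentiles of the null."""
        lo, hi = np.percentile(self.values, [2.5, 97.5])
        return float(lo), float(hi)


def build_null(
    ped: Pedigree,
    K: KinshipMatrix,
    h2: float,
    tails: Sequence[TailSpec | tuple[str, float]],
    n_replicates: int = 10_000,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> dict[TailSpec, NullDistribution]:
    """Simulate the empirical null for each tail from shared replicates.

    One set of ``n_replicates`` polygenic trait replicates (heritability
    ``h2``) is drawn on the pedigree and scored at every requested tail,
    so statistics across tails come from the same trait draws.  Tails
    given as ``(side, fraction)`` are resolved against the subject count
    (``subject_ids`` defaults to all study subjects; pass the trait's
    non-missing ids to mirror per-trait missingness).
    """
    if n_replicates < 100:
        raise ValueError(f"need at least 100 null replicates, got {n_replicates}")
    sim = simulate_polygenic(ped, K, h2, seed, n_replicates)
    values = sim.values
    if subject_ids is not None:
        values = values.loc[list(subject_ids)]
    n_subjects = values.shape[0]
    specs: list[TailSpec] = [
        t if isinstance(t, TailSpec) else TailSpec.resolve(t[0], t[1], n_subjects)
        for t in tails
    ]
    idx = K.indices(values.index)
    phi = K.phi[np.ix_(idx, idx)]
    y = values.to_numpy()  # subjects x replicates
    out: dict[TailSpec, NullDistribution] = {}
    for spec in specs:
        stats = _tail_stats_matrix(y, phi, spec)
        out[spec] = NullDistribution(
            tail=spec, h2=h2, values=stats, seed=seed, n_subjects=n_subjects
        )
    return out


def _tail_stats_matrix(y: np.ndarray, phi: np.ndarray, spec: TailSpec) -> np.ndarray:
    """Statistic per replicate column of ``y`` for one tail.

    Simulated replicates are continuous, so ties have probability zero
    and an unordered partial selection of the k most extreme values is
    equivalent to the documented id-tie-broken selection.
    """
    k = spec.n_tail
    n, r = y.shape
    if k > n:
        raise ValueError(f"tail count {k} exceeds subject count {n}")
    keys = y if spec.side == "lower" else -y
    part = np.argpartition(keys, k - 1, axis=0)[:k]  # k x r
    denom = k * (k - 1)
    stats = np.empty(r)
    for j in range(r):
        sub = phi[np.ix_(part[:, j], part[:, j])]
        stats[j] = (sub.sum() - np.trace(sub)) / denom
    return stats


def empirical_pvalue(obs: float, null: NullDistribution) -> float:
    """One-sided empirical p-value: (# null values >= obs) / N.

    The raw exceedance proportion, which can be exactly 0 when the
    observation beats every replicate; report such values with
    :func:`format_pvalue` as a bound ("< 1/N"), never as 0.
    """
    return float((null.values >= obs - _STAT_ATOL).sum() / null.n_replicates)


def format_pvalue(p: float, n_replicates: int) -> str:
    """Display form of an empirical p-value; p = 0 becomes '< 1/N'."""
    if p <= 0.0:
        return f"<{1.0 / n_replicates:g}"
    return f"{p:.4g}"


@dataclass
class RvktResult:
    """Outcome of the test for one trait and one tail."""

    trait: str
    tail: TailSpec
    observed_stat: float
    p_value: float
    tail_member_ids: list[str]
    expected_stat: float
    null_ci: tuple[float, float]
    n_replicates: int
    degenerate_ties: bool = False
    is_p_min: bool = False

    @property
    def p_display(self) -> str:
        return format_pvalue(self.p_value, self.n_replicates)


def test_trait(
    trait: pd.Series,
    K: KinshipMatrix,
    nulls: dict[TailSpec, NullDistribution],
    trait_name: str | None = None,
) -> list[RvktResult]:
    """Score one trait against pre-built nulls, one result per tail."""
    name = trait_name if trait_name is not None else str(trait.name)
    results = []
    for spec, null in nulls.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DegenerateTraitWarning)
            members = select_tail(trait, spec)
        degenerate = any(
            issubclass(w.category, DegenerateTraitWarning) for w in caught
        )
        from .pedigree import mean_pairwise_kinship

        obs = mean_pairwise_kinship(K, members)
        results.append(
            RvktResult(
                trait=name,
                tail=spec,
                observed_stat=obs,
                p_value=empirical_pvalue(obs, null),
                tail_member_ids=members,
                expected_stat=null.mean,
                null_ci=null.ci95(),
                n_replicates=null.n_replicates,
                degenerate_ties=degenerate,
            )
        )
    return results


def min_p_over_tails(
    results: Sequence[RvktResult], side: str | None = None
) -> RvktResult:
    """The result with the smallest p-value (p_min) for one side.

    Ties are broken toward the smaller tail fraction — the more extreme
    subset.  The returned result is flagged ``is_p_min``.
    """
    pool = [r for r in results if side is None or r.tail.side == side]
    if not pool:
        raise ValueError(f"no results for side {side!r}")
    best = min(pool, key=lambda r: (r.p_value, r.tail.fraction))
    best.is_p_min = True
    return best


@dataclass
class RejectionRule:
    """A one-sided rejection region chosen from a discrete empirical null.

    ``feasible`` is False when even rejecting only at the largest
    realized null value gives size above alpha; ``min_size`` then holds
    the smallest achievable size (frequency of the largest value).
    """

    alpha: float
    feasible: bool
    threshold: float | None
    size: float
    min_size: float

    def rejects(self, stat: float) -> bool:
        if not self.feasible:
            raise ValueError(
                f"no rejection region of size <= {self.alpha:g} exists; "
                f"minimum achievable size is {self.min_size:g}"
            )
        return stat >= self.threshold - _STAT_ATOL


def rejection_threshold(null: NullDistribution, alpha: float) -> RejectionRule:
    """Smallest realized null value whose exceedance proportion is <= alpha.

    The empirical CDF is discrete, so the achieved size is generally
    below alpha; it is returned alongside the threshold.  When the
    largest realized value already has frequency above alpha, no valid
    test exists at that level and an infeasibility report is returned
    (not an exception).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    vals = np.round(null.values, _STAT_DECIMALS)
    distinct, counts = np.unique(vals, return_counts=True)  # ascending
    n = null.n_replicates
    # exceedance size at each distinct value c: #(null >= c) / N
    sizes = counts[::-1].cumsum()[::-1] / n
    ok = sizes <= alpha
    min_size = float(sizes[-1])  # frequency of the largest realized value
    if not ok.any():
        return RejectionRule(
            alpha=alpha, feasible=False, threshold=None, size=1.0, min_size=min_size
        )
    j = int(np.argmax(ok))  # smallest qualifying value
    return RejectionRule(
        alpha=alpha,
        feasible=True,
        threshold=float(distinct[j]),
        size=float(sizes[j]),
        min_size=min_size,
    )


def null_support_summary(null: NullDistribution, quantile_band: float = 0.2) -> int:
    """Distinct statistic values among the top ``quantile_band`` of replicates.

    A diagnostic of CDF discreteness: simple pedigree structures put the
    statistic on a coarse lattice, so the count is small and rejection
    regions are correspondingly constrained.
    """
    if not 0.0 < quantile_band <= 1.0:
        raise ValueError(f"quantile_band must be in (0, 1], got {quantile_band}")
    m = max(1, int(round(quantile_band * null.n_replicates)))
    top = np.sort(np.round(null.values, _STAT_DECIMALS))[-m:]
    return int(np.unique(top).size)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def results_frame(results: Sequence[RvktResult]) -> pd.DataFrame:
    """Tabulate results: one row per (trait, side, tail fraction)."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "side": [r.tail.side for r in results],
            "tail_fraction": [r.tail.fraction for r in results],
            "n_tail": [r.tail.n_tail for r in results],
            "observed_stat": [r.observed_stat for r in results],
            "expected_stat": [r.expected_stat for r in results],
            "null_ci_low": [r.null_ci[0] for r in results],
            "null_ci_high": [r.null_ci[1] for r in results],
            "p_value": [r.p_value for r in results],
            "p_display": [r.p_display for r in results],
            "p_min_flag": [r.is_p_min for r in results],
            "degenerate_ties": [r.degenerate_ties for r in results],
        }
    )


def write_results(
    results: Sequence[RvktResult],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    header: str | None = None,
) -> None:
    """Write the results table (TSV) and tail membership report (JSON).

    The JSON report lists tail member ids per (trait, side, fraction) —
    the candidate list for an extreme-trait sequencing experiment.  No
    multiplicity correction across tail sizes or sides is applied within
    a trait; apply the effective-tests correction across traits to
    p_min before interpreting significance.
    """
    frame = results_frame(results)
    with open(tsv_path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# p-values are per-tail and uncorrected across tail sizes/sides\n")
        frame.to_csv(fh, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "trait": r.trait,
                "side": r.tail.side,
                "tail_fraction": r.tail.fraction,
                "n_tail": r.tail.n_tail,
                "observed_stat": r.observed_stat,
                "expected_stat": r.expected_stat,
                "null_ci": list(r.null_ci),
                "p_value": r.p_value,
                "p_display": r.p_display,
                "p_min_flag": r.is_p_min,
                "tail_member_ids": r.tail_member_ids,
            }
            for r in results
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
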