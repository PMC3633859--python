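"""Power and test-size evaluation of the kinship test by simulation.

For a chosen cohort structure, heritability, and rare-variant model,
power is estimated by (1) building one empirical null from polygenic
replicates and fixing per-tail rejection thresholds with achieved size
as close to alpha as possible without exceeding it, then (2) simulating
replicates under the rare-variant alternative and counting how often the
statistic reaches the threshold.  Power is evaluated on the tail
matching the variant's direction of effect (the screen itself always
tests both sides).

A useful design heuristic falls out of the carrier argument: power is
generally maximized when the tail size matches the expected carrier
frequency 2q(1-q) + q^2 of the rare allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    NullDistribution,
    RejectionRule,
    TailSpec,
    _STAT_ATOL,
    build_null,
    rejection_threshold,
)
from .pedigree import KinshipMatrix, Pedigree, compute_kinship
from .simulate import RareVariantSpec, TraitModel, simulate_trait

__all__ = [
    "PowerConfig",
    "PowerResult",
    "estimate_power",
    "optimal_tail_fraction",
    "write_power_grid",
]

DEFAULT_TAIL_FRACTIONS = (0.01, 0.02, 0.04, 0.06, 0.08)


def optimal_tail_fraction(q: float) -> float:
    """Tail size that tends to maximize power: the carrier frequency of q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return 2.0 * (1.0 - q) * q + q**2


@dataclass
class PowerConfig:
    """One power-experiment cell.

    ``n_null`` polygenic replicates set the thresholds; ``n_alt``
    rare-variant replicates estimate power.  Defaults mirror the
    standard experiment: tails of 1-8%, alpha 0.05, 10,000 null and
    1,000 alternative replicates.
    """

    ped: Pedigree
    h2: float
    variant: RareVariantSpec
    tail_fractions: Sequence[float] = DEFAULT_TAIL_FRACTIONS
    alpha: float = 0.05
    n_null: int = 10_000
    n_alt: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alt < 100:
            raise ValueError(f"need at least 100 alternative replicates, got {self.n_alt}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class PowerResult:
    """Per-tail power estimates plus the best tail and carrier enrichment."""

    config: PowerConfig
    table: pd.DataFrame  # one row per tail fraction
    best_tail: float | None
    carrier_enrichment: float | None

    @property
    def best_power(self) -> float | None:
        if self.best_tail is None:
            return None
        row = self.table[self.table["tail_fraction"] == self.best_tail]
        return float(row["power"].iloc[0])


def estimate_power(
    config: PowerConfig,
    K: KinshipMatrix | None = None,
    nulls: dict[TailSpec, NullDistribution] | None = None,
) -> PowerResult:
    """Estimate power of the test for one parameter cell.

    ``nulls`` may be supplied to reuse one null distribution across
    parameter cells that share (cohort, h2) — the standard experimental
    design.  A tail whose threshold is infeasible at alpha (the
    discreteness pathology) gets power NaN and its minimum achievable
    size in the table.
    """
    ped = config.ped
    if K is None:
        K = compute_kinship(ped)
    ss = np.random.SeedSequence(config.seed)
    seed_null, seed_alt = ss.spawn(2)
    subjects = ped.study_subject_ids
    n_subjects = len(subjects)
    side = "upper" if config.variant.direction == "raise" else "lower"
    specs = [TailSpec.resolve(side, f, n_subjects) for f in config.tail_fractions]
    if nulls is None:
        nulls = build_null(
            ped, K, config.h2, specs, n_replicates=config.n_null, seed=seed_null
        )
    rules: dict[TailSpec, RejectionRule] = {
        spec: rejection_threshold(nulls[spec], config.alpha) for spec in specs
    }

    model = TraitModel(h2=config.h2, rare_variant=config.variant)
    sim = simulate_trait(ped, K, model, n_replicates=config.n_alt, seed=seed_alt)
    y = sim.values.loc[subjects].to_numpy()
    carriers = (sim.carrier_status.loc[subjects].to_numpy() > 0)
    idx = K.indices(subjects)
    phi = K.phi[np.ix_(idx, idx)]

    rows = []
    for spec in specs:
        stats, tail_idx = _tail_stats_and_members(y, phi, spec)
        enrich = float(np.take_along_axis(carriers, tail_idx, axis=0).mean())
        rule = rules[spec]
        if rule.feasible:
            power = float((stats >= rule.threshold - _STAT_ATOL).mean())
            mc_se = float(np.sqrt(power * (1.0 - power) / config.n_alt))
        else:
            power, mc_se = float("nan"), float("nan")
        rows.append(
            {
                "tail_fraction": spec.fraction,
                "n_tail": spec.n_tail,
                "side": spec.side,
                "power": power,
                "mc_se": mc_se,
                "threshold": rule.threshold,
                "achieved_size": rule.size if rule.feasible else float("nan"),
                "feasible": rule.feasible,
                "min_achievable_size": rule.min_size,
                "carrier_enrichment": enrich,
            }
        )
    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    if len(feasible) and feasible["power"].notna().any():
        best_row = feasible.loc[feasible["power"].idxmax()]
        best_tail = float(best_row["tail_fraction"])
        best_enrich = float(best_row["carrier_enrichment"])
    else:
        best_tail, best_enrich = None, None
    return PowerResult(
        config=config, table=table, best_tail=best_tail, carrier_enrichment=best_enrich
    )


def _tail_stats_and_members(y: np.ndarray, phi: np.ndarray, spec: TailSpec):
    """Per-replicate tail statistic and tail member indices.

    Like the null machinery, but also returns the (n_tail x replicates)
    member index matrix so carrier enrichment can be scored on the same
    tails.
    """
    k = spec.n_tail
    keys = y if spec.side == "lower" else -y
    part = np.argpartition(keys, k - 1, axis=0)[:k]
    denom = k * (k - 1)
    stats = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        sub = phi[np.ix_(part[:, j], part[:, j])]
        stats[j] = (sub.sum() - np.trace(sub)) / denom
    return stats, part


def write_power_grid(
    results: Sequence[PowerResult], path: str | Path, header: str | None = None
) -> None:
    """Write a grid of power results as TSV, one row per (cell, tail)."""
    frames = []
    for res in results:
        t = res.table.copy()
        t.insert(0, "q", res.config.variant.q)
        t.insert(1, "v", res.config.variant.variance_fraction(res.config.h2))
        t.insert(2, "h2", res.config.h2)
        t.insert(3, "alpha", res.config.alpha)
        t["n_null"] = res.config.n_null
        t["n_alt"] = res.config.n_alt
        t["seed"] = res.config.seed
        t["best_tail"] = res.best_tail
        frames.append(t)
    grid = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        grid.to_csv(fh, sep="\t", index=False)
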