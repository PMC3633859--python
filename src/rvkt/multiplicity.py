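"""Multiple-testing correction across correlated traits.

Screening dozens of traits multiplies the chance of a spurious p_min.
Traits are often correlated, so plain Bonferroni over the trait count is
too harsh; instead the effective number of independent tests M_eff is
derived from the eigenvalues of the trait-trait correlation matrix
(Li & Ji's estimator): an eigenvalue contributes its integer part as
whole tests (capped at 1) plus its fractional part,

    M_eff = sum_i [ I(|lam_i| >= 1) + (|lam_i| - floor(|lam_i|)) ].

M independent traits give M_eff = M; M copies of one trait give 1.
p_min per trait is then Bonferroni-corrected by M_eff.

Caveat printed with every report: p_min is itself the minimum over the
tail sizes and sides searched within a trait, and no correction is
applied for that search — only for the number of traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MultiplicityReport", "effective_tests", "correct_pmin"]

SEARCH_CAVEAT = (
    "p_min is the minimum over tail sizes and sides within each trait; "
    "the correction accounts for the number of traits only."
)


@dataclass
class EffectiveTests:
    """Li-Ji effective number of tests, raw and ceiling-rounded."""

    m_traits: int
    m_eff_raw: float
    m_eff: int  # ceiling of raw; used for correction
    excluded: list[str]  # constant / all-missing traits dropped

    def __post_init__(self) -> None:
        if not 1 <= self.m_eff <= max(self.m_traits, 1):
            raise ValueError(
                f"M_eff = {self.m_eff} outside [1, M = {self.m_traits}]"
            )


def effective_tests(
    trait_table: pd.DataFrame, min_pairwise_n: int = 30
) -> EffectiveTests:
    """Effective number of independent tests among the trait columns.

    Correlations are computed on pairwise-complete observations (each
    pair must overlap in at least ``min_pairwise_n`` subjects).
    Constant or all-missing traits are excluded with a warning before
    the eigen-analysis.
    """
    if trait_table.shape[1] < 2:
        raise ValueError("need at least 2 traits for an effective-tests estimate")
    excluded = [
        c
        for c in trait_table.columns
        if trait_table[c].dropna().nunique() < 2
    ]
    if excluded:
        warnings.warn(
            f"excluding constant or empty traits from M_eff: {excluded}",
            UserWarning,
            stacklevel=2,
        )
    table = trait_table.drop(columns=excluded)
    m = table.shape[1]
    if m < 2:
        raise ValueError("fewer than 2 usable traits after exclusions")
    notna = table.notna().to_numpy().astype(float)
    overlap = notna.T @ notna
    off = overlap[~np.eye(m, dtype=bool)]
    if (off < min_pairwise_n).any():
        bad = int((off < min_pairwise_n).sum() // 2)
        raise ValueError(
            f"{bad} trait pairs overlap in fewer than {min_pairwise_n} "
            "subjects; correlations are not estimable"
        )
    corr = table.corr(method="pearson", min_periods=min_pairwise_n).to_numpy()
    # round at 1e-10 so a numerically-4.0 eigenvalue does not leak a
    # spurious fractional part through floor()
    lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 10)
    m_eff_raw = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return EffectiveTests(
        m_traits=m,
        m_eff_raw=m_eff_raw,
        m_eff=int(math.ceil(m_eff_raw - 1e-9)),
        excluded=excluded,
    )


@dataclass
class MultiplicityReport:
    """Corrected p_min per trait with significance flags at alpha."""

    m_traits: int
    m_eff: int
    m_eff_raw: float
    alpha: float
    table: pd.DataFrame  # trait, p_min, p_min_corrected, significant
    caveat: str = SEARCH_CAVEAT

    def significant_traits(self) -> list[str]:
        return self.table.loc[self.table["significant"], "trait"].tolist()

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# M = {self.m_traits} traits, M_eff = {self.m_eff} "
                     f"(raw {self.m_eff_raw:.4f}), alpha = {self.alpha:g}\n")
            fh.write(f"# {self.caveat}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def correct_pmin(
    p_min: Mapping[str, float] | pd.Series,
    m_eff: int | EffectiveTests,
    alpha: float = 0.05,
) -> MultiplicityReport:
    """Bonferroni-correct per-trait p_min by the effective test count.

    p_min_corrected = min(1, p_min * M_eff); traits with corrected p at
    or below alpha are flagged significant.  Rows are ordered by
    corrected p.
    """
    series = pd.Series(p_min, dtype=float)
    if ((series < 0) | (series > 1)).any():
        raise ValueError("p_min values must be in [0, 1]")
    if isinstance(m_eff, EffectiveTests):
        m_eff_raw, m_eff_int, m_traits = m_eff.m_eff_raw, m_eff.m_eff, m_eff.m_traits
    else:
        m_eff_int = int(m_eff)
        m_eff_raw = float(m_eff)
        m_traits = len(series)
        if m_eff_int < 1:
            raise ValueError(f"M_eff must be >= 1, got {m_eff_int}")
    corrected = np.minimum(1.0, series * m_eff_int)
    table = pd.DataFrame(
        {
            "trait": series.index,
            "p_min": series.to_numpy(),
            "p_min_corrected": corrected.to_numpy(),
            "significant": corrected.to_numpy() <= alpha,
        }
    ).sort_values("p_min_corrected", kind="stable", ignore_index=True)
    return MultiplicityReport(
        m_traits=m_traits,
        m_eff=m_eff_int,
        m_eff_raw=m_eff_raw,
        alpha=alpha,
        table=table,
    )
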