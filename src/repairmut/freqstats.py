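"""Mutation-frequency statistics: frequencies, Fisher exact, Bonferroni.

Mutation frequency is the percent of screened colonies that are white with
an undeleted episome.  Condition contrasts use the two-sided Fisher exact
test on 2x2 tables of (white-undeleted, blue) counts, Bonferroni-corrected
within a comparison family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "FrequencyResult",
    "mutation_frequency",
    "aggregate_frequencies",
    "fisher_exact_two_sided",
    "bonferroni",
    "fold_change",
]


def mutation_frequency(n_white_undeleted: int, n_total: int) -> float:
    """Percent white colonies with undeleted episomes per total screened."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_white_undeleted <= n_total):
        raise ValueError(
            f"n_white_undeleted={n_white_undeleted} outside [0, {n_total}]"
        )
    return 100.0 * n_white_undeleted / n_total


def aggregate_frequencies(frequencies) -> tuple[float, float]:
    """Mean and standard error of per-transfection frequencies.

    SEM is sample standard deviation / sqrt(n); NaN for a single value.
    """
    values = np.asarray(list(frequencies), dtype=float)
    if values.size == 0:
        raise ValueError("no frequencies to aggregate")
    mean = float(values.mean())
    if values.size == 1:
        return mean, float("nan")
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, sem


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one, with a relative tie tolerance of 1e-12
    (the minimum-likelihood convention).
    """
    for cell in (a, b, c, d):
        if cell < 0:
            raise ValueError("negative cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all margins zero")
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # log space: extreme tables underflow the linear pmf to exactly zero
    logpmf = hypergeom.logpmf(support, n, col1, row1)
    log_observed = logpmf[a - lo]
    selected = logpmf[logpmf <= log_observed + math.log1p(1e-12)]
    p = float(np.exp(logsumexp(selected)))
    return min(max(p, math.ulp(0.0)), 1.0)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p: ``min(1, p * m)`` for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p} outside (0, 1]")
    return min(1.0, p * m)


def fold_change(freq_lesion: float, freq_control: float) -> float:
    """Ratio of lesion to control mutation frequency."""
    if freq_control == 0:
        warnings.warn("zero control frequency; fold change infinite", stacklevel=2)
        return float("inf")
    return freq_lesion / freq_control


@dataclass
class FrequencyResult:
    """Per-condition frequency summary plus pairwise comparisons."""

    condition: str
    frequencies: list[float] = field(default_factory=list)  # percent, per transfection
    mean: float = float("nan")
    sem: float = float("nan")
    comparisons: list[dict] = field(default_factory=list)

    @classmethod
    def from_counts(cls, condition: str, counts) -> "FrequencyResult":
        """Build from an iterable of (n_white_undeleted, n_total) pairs."""
        freqs = [mutation_frequency(w, t) for w, t in counts]
        mean, sem = aggregate_frequencies(freqs)
        return cls(condition=condition, frequencies=freqs, mean=mean, sem=sem)

    def compare(
        self,
        other: "FrequencyResult",
        self_counts: tuple[int, int],
        other_counts: tuple[int, int],
        family_size: int = 1,
    ) -> dict:
        """Fisher-exact contrast on pooled (white-undeleted, blue) counts."""
        a, total_a = self_counts
        c, total_c = other_counts
        p = fisher_exact_two_sided(a, total_a - a, c, total_c - c)
        comparison = {
            "condition_a": self.condition,
            "condition_b": other.condition,
            "fisher_p_two_sided": p,
            "bonferroni_adjusted_p": bonferroni(p, family_size),
            "fold_change": fold_change(self.mean, other.mean),
        }
        self.comparisons.append(comparison)
        return comparison
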