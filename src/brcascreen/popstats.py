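"""Population burden metrics and cross-dataset comparisons.

Conventions
-----------
* The per-person P/LP rate is the number of distinct P/LP variants divided by
  the cohort size (a variant-count rate, not an allele-count rate).
* The accumulated frequency of a variant set is the plain sum of its allele
  frequencies — an upper proxy for the carrier frequency when variants are
  rare and independent.
* Reported rates are displayed to 3 significant figures, truncating toward
  zero (the convention of the printed panel summaries this module reproduces);
  :func:`sig_trunc` implements it, and all returned values stay exact.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .variants import TrimmedVariant

__all__ = [
    "DatasetSummary",
    "TestResult",
    "FoldEnrichment",
    "plp_rate",
    "accumulated_frequency",
    "fold_enrichment",
    "dataset_overlap",
    "pearson_r",
    "coding_fraction",
    "sig_trunc",
]


@dataclass
class TestResult:
    """One statistical test or descriptive diagnostic."""

    method: str
    statistic: float
    p_value: float | None = None
    table: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass
class DatasetSummary:
    """Burden summary for one frequency panel."""

    tag: str
    n_individuals: int
    plp_count: int
    plp_rate: float = field(init=False)
    accumulated_frequency: float = 0.0

    def __post_init__(self) -> None:
        self.plp_rate = plp_rate(self.plp_count, self.n_individuals)


def plp_rate(plp_count: int, n_individuals: int) -> float:
    """Distinct P/LP variants per person: ``plp_count / n_individuals``."""
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if plp_count < 0:
        raise ValueError(f"plp_count must be >= 0, got {plp_count}")
    return plp_count / n_individuals


def accumulated_frequency(freqs: Iterable[float]) -> float:
    """Exact (compensated) sum of allele frequencies."""
    freqs = list(freqs)
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency out of [0,1]: {f}")
    return math.fsum(freqs)


@dataclass(frozen=True)
class FoldEnrichment:
    """AF ratio between a target and a reference dataset.

    ``ratio`` is None when the reference frequency is zero: the variant is
    flagged as absent from the reference ("novel in target") or, when both
    frequencies are zero, as undefined.
    """

    ratio: float | None
    flag: Literal["ok", "novel_in_target", "undefined"] = "ok"


def fold_enrichment(af_target: float, af_reference: float) -> FoldEnrichment:
    if af_target < 0 or af_reference < 0:
        raise ValueError("allele frequencies must be non-negative")
    if af_reference == 0:
        if af_target == 0:
            return FoldEnrichment(None, "undefined")
        return FoldEnrichment(None, "novel_in_target")
    return FoldEnrichment(af_target / af_reference)


def dataset_overlap(
    a: Iterable[TrimmedVariant], b: Iterable[TrimmedVariant]
) -> list[TrimmedVariant]:
    """Variants present in both sets (exact key intersection, sorted)."""
    keys_b = {v.key for v in b}
    shared = {v.key: v for v in a if v.key in keys_b}
    return [shared[k] for k in sorted(shared)]


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    transform_x: str | None = None,
    transform_y: str | None = None,
) -> TestResult:
    """Product-moment correlation with pairwise deletion of missing values.

    ``transform_*`` may be ``"neglog10"``, mapping f to −log10(f) (all values
    must be positive); used for correlating scores against reverse-log allele
    frequencies.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    for name, arr, tr in (("x", xa, transform_x), ("y", ya, transform_y)):
        if tr is None:
            continue
        if tr != "neglog10":
            raise ValueError(f"unknown transform {tr!r}")
        if np.any(arr <= 0):
            raise ValueError(f"neglog10 transform of {name} requires positive values")
    if transform_x == "neglog10":
        xa = -np.log10(xa)
    if transform_y == "neglog10":
        ya = -np.log10(ya)
    if xa.size < 3:
        raise ValueError(f"need at least 3 complete pairs, have {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(xa, ya)
    return TestResult(method="pearson", statistic=float(r), p_value=float(p))


def coding_fraction(
    cds_lengths: Sequence[float], regions: Sequence
) -> float:
    """Percentage of the gene regions occupied by coding sequence.

    ``100 * sum(cds_lengths) / sum(region lengths)`` with regions taken as
    1-based inclusive intervals.
    """
    if not list(cds_lengths) or not list(regions):
        raise ValueError("cds_lengths and regions must be non-empty")
    if any(l <= 0 for l in cds_lengths):
        raise ValueError("coding lengths must be positive")
    total_region = sum(r.end - r.start + 1 for r in regions)
    return 100.0 * sum(cds_lengths) / total_region


def sig_trunc(x: float, n: int = 3) -> float:
    """Truncate ``x`` toward zero to ``n`` significant figures.

    This is the display convention for per-person rates (e.g. 10/3552 =
    2.8153e-3 prints as 2.81e-3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    # decimal arithmetic avoids binary-float artifacts like 0.0003 -> 0.000299
    d = decimal.Decimal(repr(x))
    shift = d.adjusted() - n + 1
    q = d.scaleb(-shift).to_integral_value(rounding=decimal.ROUND_DOWN).scaleb(shift)
    return float(q)
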