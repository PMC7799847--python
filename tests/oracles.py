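"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — direct enumeration, closed-form
formulas, exact rational arithmetic — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# variant representation oracles
# ---------------------------------------------------------------------------

def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply one edit to a sequence whose first base is position 1."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "REF does not match sequence"
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def minimal_leftmost_representation(
    seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Enumerate every VCF-valid (pos', ref', alt') producing the same edited
    haplotype; return the one with the smallest total allele length, breaking
    ties by the left-most position."""
    edited = apply_edit(seq, pos, ref, alt)
    n, m = len(seq), len(edited)
    best = None
    for p in range(1, n + 1):
        if seq[: p - 1] != edited[: p - 1]:
            break
        for ref_len in range(0, n - p + 2):
            cand_ref = seq[p - 1 : p - 1 + ref_len]
            alt_len = m - (n - ref_len)
            if alt_len < 0:
                continue
            cand_alt = edited[p - 1 : p - 1 + alt_len]
            if not cand_ref or not cand_alt or cand_ref == cand_alt:
                continue
            if seq[: p - 1] + cand_alt + seq[p - 1 + ref_len :] != edited:
                continue
            key = (len(cand_ref) + len(cand_alt), p)
            if best is None or key < best[0]:
                best = (key, (p, cand_ref, cand_alt))
    assert best is not None, "no valid representation found"
    return best[1]


# ---------------------------------------------------------------------------
# 2x2 test oracles
# ---------------------------------------------------------------------------

def hypergeom_pmf_exact(x: int, N: int, r: int, c: int) -> Fraction:
    """P(X = x) for the number of row-1/column-1 cases with fixed margins."""
    return Fraction(math.comb(r, x) * math.comb(N - r, c - x), math.comb(N, c))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over same-margin tables with
    exact rational probabilities (tables no more probable than observed,
    within relative tolerance 1e-7)."""
    N, r, c1 = a + b + c + d, a + b, a + c
    if N == 0:
        return 1.0
    lo, hi = max(0, r + c1 - N), min(r, c1)
    p_obs = hypergeom_pmf_exact(a, N, r, c1)
    tol = Fraction(10**7 + 1, 10**7)  # 1 + 1e-7, exactly
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = hypergeom_pmf_exact(x, N, r, c1)
        if p <= p_obs * tol:
            total += p
    return float(min(total, Fraction(1)))


def yates_chi2_closed_form(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-squared statistic and p via the 2x2 closed form;
    the chi^2_1 upper tail is erfc(sqrt(x/2))."""
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = max(abs(a * d - b * c) - N / 2, 0.0) ** 2
    stat = N * num / denom
    return stat, math.erfc(math.sqrt(stat / 2))


def chi2_uncorrected_closed_form(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = N * (a * d - b * c) ** 2 / denom
    return stat, math.erfc(math.sqrt(stat / 2))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) by term-by-term summation with log-space coefficients."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        log_term = (
            math.lgamma(n + 1)
            - math.lgamma(i + 1)
            - math.lgamma(n - i + 1)
            + i * math.log(p0)
            + (n - i) * math.log1p(-p0)
        )
        total += math.exp(log_term)
    return min(total, 1.0)


def pearson_r_formula(x, y) -> float:
    """Plain covariance / (sigma_x sigma_y) from first principles."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def compensated_sum(values) -> float:
    """Kahan summation."""
    total = 0.0
    comp = 0.0
    for v in values:
        y = v - comp
        t = total + y
        comp = (t - total) - y
        total = t
    return total
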