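"""Questionnaire QC and carrier-versus-cohort family-history analysis.

The questionnaire table holds one row per participant with boolean cancer
history items named ``<category>__<site>`` (categories: self, father, mother,
brother, sister, offspring, spouse).  Participants who checked more than 50
malignant-neoplasm items are dropped during QC — such records are dominated by
contradictory answers.  Contradictions themselves (e.g. a male participant
reporting a self history of ovarian cancer) are flagged but never drop a
record on their own.

For each relative category the screen builds a carrier-versus-non-carrier 2×2
table of participants ("positive" = any checked item in that category;
participant-level counting, since the questionnaire cannot weight multiple
affected siblings) and tests for a preponderance of cancer history among
carriers.  The default test is the chi-squared test with Yates' continuity
correction, switching to Fisher's exact test when any expected cell count is
below 5; a one-sided binomial tail against the non-carrier positive proportion
is reported as a secondary check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popstats import TestResult

__all__ = [
    "CATEGORIES",
    "BLOOD_RELATIVES",
    "FEMALE_SPECIFIC_SITES",
    "Contingency2x2",
    "QcReport",
    "qc_records",
    "category_positive",
    "build_contingency",
    "yates_chi2",
    "fisher_exact",
    "binomial_tail",
    "family_history_screen",
]

CATEGORIES = ("self", "father", "mother", "brother", "sister", "offspring", "spouse")
# "family" positivity: any blood relative, excluding the participant and spouse
BLOOD_RELATIVES = ("father", "mother", "brother", "sister", "offspring")
FEMALE_SPECIFIC_SITES = frozenset({"ovary", "cervix", "uterus", "endometrium", "vulva"})
MALE_CATEGORIES = frozenset({"father", "brother"})


@dataclass(frozen=True)
class Contingency2x2:
    """Participant counts: (carrier, non-carrier) × (positive, negative)."""

    a: int  # carrier & positive
    b: int  # carrier & negative
    c: int  # non-carrier & positive
    d: int  # non-carrier & negative

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected_min(self) -> float:
        r1, r2, c1, c2 = self.margins
        if self.n == 0:
            return 0.0
        return min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / self.n

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _item_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if "__" in c and c.split("__", 1)[0] in CATEGORIES]


@dataclass
class QcReport:
    dropped: pd.DataFrame        # participant_id, n_checked
    contradictions: pd.DataFrame  # participant_id, item


def qc_records(
    records: pd.DataFrame, max_items: int = 50
) -> tuple[pd.DataFrame, QcReport]:
    """Drop participants who checked more than ``max_items`` cancer items.

    The inequality is strict: exactly ``max_items`` checked items is retained.
    Sex-contradictory answers (male self-history of a female-specific cancer)
    are listed in the report but do not cause a drop.
    """
    items = _item_columns(records)
    checked = records[items].astype(int).sum(axis=1)
    over = checked > max_items
    dropped = pd.DataFrame(
        {
            "participant_id": records.loc[over, "participant_id"].to_numpy(),
            "n_checked": checked[over].to_numpy(),
        }
    )
    contr_rows = []
    male = records["sex"].astype(str).str.lower().eq("male")
    for col in items:
        cat, site = col.split("__", 1)
        female_only = site in FEMALE_SPECIFIC_SITES
        if not female_only:
            continue
        if cat == "self":
            bad = male & records[col].astype(bool)
        elif cat in MALE_CATEGORIES:
            bad = records[col].astype(bool)
        else:
            continue
        for pid in records.loc[bad, "participant_id"]:
            contr_rows.append({"participant_id": pid, "item": col})
    report = QcReport(
        dropped=dropped,
        contradictions=pd.DataFrame(contr_rows, columns=["participant_id", "item"]),
    )
    return records.loc[~over].reset_index(drop=True), report


def category_positive(records: pd.DataFrame, category: str) -> pd.Series:
    """Boolean per-participant positivity for one category.

    ``"any_family"`` means any checked item among blood-relative categories
    (father/mother/brother/sister/offspring); spouse-only positives do not
    count, and neither does the participant's own history.
    """
    items = _item_columns(records)
    if category == "any_family":
        cols = [c for c in items if c.split("__", 1)[0] in BLOOD_RELATIVES]
    elif category in CATEGORIES:
        cols = [c for c in items if c.split("__", 1)[0] == category]
    else:
        raise ValueError(f"unknown category {category!r}")
    if not cols:
        raise ValueError(f"no questionnaire items for category {category!r}")
    return records[cols].astype(bool).any(axis=1)


def build_contingency(records: pd.DataFrame, category: str) -> Contingency2x2:
    """Carrier × category-positivity table, counting participants once each."""
    pos = category_positive(records, category)
    carrier = records["carrier"].astype(bool)
    return Contingency2x2(
        a=int((carrier & pos).sum()),
        b=int((carrier & ~pos).sum()),
        c=int((~carrier & pos).sum()),
        d=int((~carrier & ~pos).sum()),
    )


def yates_chi2(t: Contingency2x2, correction: bool = True) -> TestResult:
    """Chi-squared test on a 2×2 table, with Yates' continuity correction.

    chi2 = N * max(|ad - bc| - N/2, 0)^2 / ((a+b)(c+d)(a+c)(b+d)); without the
    correction the N/2 term is omitted.  All margins must be positive.
    """
    if any(m == 0 for m in t.margins):
        raise ValueError(
            "a zero margin makes the chi-squared test undefined; use fisher_exact"
        )
    stat, p, _, _ = stats.chi2_contingency(t.as_array(), correction=correction)
    return TestResult(
        method="chi2_yates" if correction else "chi2",
        statistic=float(stat),
        p_value=float(p),
        table=(t.a, t.b, t.c, t.d),
    )


def fisher_exact(t: Contingency2x2) -> TestResult:
    """Two-sided Fisher's exact test (sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one)."""
    odds, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(odds) if np.isfinite(odds) else float("nan"),
        p_value=float(p),
        table=(t.a, t.b, t.c, t.d),
    )


def binomial_tail(k: int, n: int, p0: float) -> TestResult:
    """One-sided upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError(f"background proportion must be in (0,1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = float(stats.binom.sf(k - 1, n, p0))
    return TestResult(method="binomial_tail", statistic=float(k), p_value=min(p, 1.0))


def _stars(p: float | None) -> str:
    if p is None:
        return ""
    if p < 1e-4:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def family_history_screen(
    records: pd.DataFrame,
    categories: Sequence[str] = CATEGORIES + ("any_family",),
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-category carrier-enrichment tests.

    For each category: the 2×2 table, the default test (Yates chi-squared, or
    Fisher's exact when any expected cell is below 5), the secondary one-sided
    binomial tail with the non-carrier positive proportion as background, and
    significance stars at 0.05 / 1e-4.  No multiple-testing correction is
    applied unless ``bonferroni`` is set.
    """
    if not records["carrier"].astype(bool).any():
        raise ValueError("no carriers among the records")
    m = len(categories)
    rows = []
    for cat in categories:
        t = build_contingency(records, cat)
        if t.expected_min() < 5 or any(mg == 0 for mg in t.margins):
            primary = fisher_exact(t)
        else:
            primary = yates_chi2(t)
        p = primary.p_value
        if bonferroni and p is not None:
            p = min(1.0, p * m)
        n_carrier = t.a + t.b
        n_non = t.c + t.d
        if n_non > 0 and 0 < t.c < n_non:
            binom_p = binomial_tail(t.a, n_carrier, t.c / n_non).p_value
        else:
            binom_p = None
        rows.append(
            {
                "category": cat,
                "carrier_pos": t.a,
                "carrier_neg": t.b,
                "noncarrier_pos": t.c,
                "noncarrier_neg": t.d,
                "method": primary.method,
                "statistic": primary.statistic,
                "p_value": p,
                "binomial_p": binom_p,
                "significant": p is not None and p < alpha,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)
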