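"""Phenotype enrichment between family-containing and other strains.

For every categorical trait, each category with enough in-family observations
gets a one-vs-rest 2x2 Fisher exact test (family membership x category);
quantitative traits get a classic pooled-variance two-sample Student t-test.
Strains missing a trait's value are excluded from that trait's test. No
multiple-testing correction is applied to the headline p-values (Bonferroni
and Benjamini-Hochberg columns are emitted for information only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import StrainTraitTable

MIN_FAMILY_COUNT_DEFAULT = 5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: in-family / not-in-family. Columns: has-category / lacks-category."""

    a: int  # family, category
    b: int  # family, other
    c: int  # non-family, category
    d: int  # non-family, other

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one."""
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        warnings.warn("degenerate margin; p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def student_t_test(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Classic pooled-variance two-sample t-test, df = n_a + n_b - 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, df=len(a) + len(b) - 2, p=1.0)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=len(a) + len(b) - 2, p=float(res.pvalue))


def enrichment_scan(
    table: StrainTraitTable, min_count: int = MIN_FAMILY_COUNT_DEFAULT
) -> pd.DataFrame:
    """Test every trait for differential representation between family and
    non-family strains.

    Categorical categories with fewer than ``min_count`` in-family strains
    are marked not-tested (mirroring how sparse cells are usually reported
    rather than tested). Returns one row per (trait, category) or
    quantitative trait, with counts/means, p-values, and informational
    Bonferroni / Benjamini-Hochberg columns.
    """
    rows = []
    member = table.membership
    for trait in table.categorical_traits:
        col = table.data[trait]
        ok = col.notna()
        for category in sorted(col[ok].unique()):
            in_cat = ok & (col == category)
            a = int((member & in_cat).sum())
            b = int((member & ok & ~in_cat).sum())
            c = int((~member & in_cat).sum())
            d = int((~member & ok & ~in_cat).sum())
            tested = a >= min_count
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)) if tested else np.nan
            rows.append(
                {
                    "trait": trait,
                    "category": category,
                    "kind": "categorical",
                    "family_count": a,
                    "family_total": a + b,
                    "other_count": c,
                    "other_total": c + d,
                    "family_mean": np.nan,
                    "other_mean": np.nan,
                    "tested": tested,
                    "p": p,
                }
            )
    for trait in table.quantitative_traits:
        col = table.data[trait]
        fam = col[member & col.notna()].to_numpy(dtype=float)
        oth = col[~member & col.notna()].to_numpy(dtype=float)
        tested = len(fam) >= 2 and len(oth) >= 2
        p = student_t_test(fam, oth).p if tested else np.nan
        rows.append(
            {
                "trait": trait,
                "category": None,
                "kind": "quantitative",
                "family_count": len(fam),
                "family_total": len(fam),
                "other_count": len(oth),
                "other_total": len(oth),
                "family_mean": float(fam.mean()) if len(fam) else np.nan,
                "other_mean": float(oth.mean()) if len(oth) else np.nan,
                "tested": tested,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        tested_mask = out["tested"] & out["p"].notna()
        m = int(tested_mask.sum())
        out["p_bonferroni"] = np.nan
        out["p_bh"] = np.nan
        if m:
            ps = out.loc[tested_mask, "p"].to_numpy()
            out.loc[tested_mask, "p_bonferroni"] = np.minimum(ps * m, 1.0)
            out.loc[tested_mask, "p_bh"] = stats.false_discovery_control(ps, method="bh")
    return out
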