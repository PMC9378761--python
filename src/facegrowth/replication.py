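"""Cross-cohort comparison of growth-pattern frequency tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcordanceReport", "modal_concordance"]

_COUNT_COLS = ["n1", "n2", "n3", "n4", "n5"]


@dataclass
class ConcordanceReport:
    per_phenotype: pd.DataFrame  # phenotype, modal_1, modal_2, tie flags, agree, chi2_distance
    n_agree: int
    n_phenotypes: int

    @property
    def fraction_agree(self) -> float:
        return self.n_agree / self.n_phenotypes

    def summary(self) -> str:
        return (
            f"{self.n_agree}/{self.n_phenotypes} phenotypes "
            f"({self.fraction_agree:.1%}) share the modal growth pattern"
        )


def _modal(counts: np.ndarray) -> tuple[int, bool]:
    """Modal code 1..5; ties broken toward the lower code and flagged."""
    best = counts.max()
    winners = np.flatnonzero(counts == best)
    return int(winners[0]) + 1, len(winners) > 1


def _chi2_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    """Symmetric chi-square distance between the two proportion vectors."""
    p1 = c1 / c1.sum() if c1.sum() else np.zeros(5)
    p2 = c2 / c2.sum() if c2.sum() else np.zeros(5)
    denom = p1 + p2
    ok = denom > 0
    return float(0.5 * np.sum((p1[ok] - p2[ok]) ** 2 / denom[ok]))


def modal_concordance(table1: pd.DataFrame, table2: pd.DataFrame) -> ConcordanceReport:
    """Per-phenotype modal-pattern agreement between two frequency tables.

    Both tables must be pattern_table-style frames sharing the same
    phenotype set (any order) with count columns n1..n5.  Counts and
    proportions give identical reports (only ratios matter).
    """
    s1 = set(table1["phenotype"])
    s2 = set(table2["phenotype"])
    if s1 != s2:
        raise ValueError(
            f"phenotype sets differ: only-in-1={sorted(s1 - s2)}, "
            f"only-in-2={sorted(s2 - s1)}"
        )
    t1 = table1.set_index("phenotype")
    t2 = table2.set_index("phenotype")
    rows = []
    for pheno in sorted(s1):
        c1 = t1.loc[pheno, _COUNT_COLS].to_numpy(dtype=float)
        c2 = t2.loc[pheno, _COUNT_COLS].to_numpy(dtype=float)
        m1, tie1 = _modal(c1)
        m2, tie2 = _modal(c2)
        rows.append((pheno, m1, m2, tie1, tie2, m1 == m2, _chi2_distance(c1, c2)))
    per = pd.DataFrame(
        rows,
        columns=["phenotype", "modal_1", "modal_2", "tie_1", "tie_2",
                 "agree", "chi2_distance"],
    )
    return ConcordanceReport(per, int(per["agree"].sum()), len(per))
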