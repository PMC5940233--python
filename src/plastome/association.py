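"""Habitat × gene-presence association screen.

For each gene the survey is collapsed to a 2×2 contingency table
(rows: marine, freshwater; columns: present, absent) and summarized by
two statistics:

* the **concordance rate** — the fraction of species whose state
  matches the better of the two habitat-specific patterns
  ("retained in marine, lost in freshwater" or the reverse), i.e.
  ``max(p_mp + n_fa, p_fp + n_ma) / n`` — always ≥ 0.5 by construction;
* the **Pearson chi-square test** on the table (df = 1), with optional
  Yates continuity correction, significant at p < alpha (default 0.01).

Brackish species do not fit a two-habitat contrast; the policy for
them (exclude, count as marine, count as freshwater) is explicit and
recorded on every result.  Degenerate tables (a zero row or column
margin) yield p = 1 with a degeneracy flag instead of an exception so
that genome-wide screens never abort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import PresenceMatrix

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "AssociationResult",
    "contingency_table",
    "concordance_rate",
    "chi_square_test",
    "screen_genes",
    "results_table",
    "write_results",
]

BrackishPolicy = Literal["exclude", "as_marine", "as_freshwater"]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 habitat × presence counts.

    Layout: rows (marine, freshwater) × columns (present, absent), so
    ``a`` = marine & present, ``b`` = marine & absent, ``c`` =
    freshwater & present, ``d`` = freshwater & absent.
    """

    a: int
    b: int
    c: int
    d: int
    n_excluded_brackish: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (chi2 undefined)."""
        arr = self.as_array()
        return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    table: ContingencyTable
    concordance: float
    direction: str  # "marine_retained" | "freshwater_retained"
    chi2: float
    df: int
    p_value: float
    significant: bool
    degenerate: bool = False
    p_adjusted: float | None = None


def contingency_table(
    matrix: PresenceMatrix,
    gene: str,
    brackish_policy: BrackishPolicy = "exclude",
) -> ContingencyTable:
    """Tally one gene's presence by habitat into a 2×2 table."""
    if gene not in matrix.presence.columns:
        raise KeyError(f"gene {gene!r} not in matrix")
    counts = {"a": 0, "b": 0, "c": 0, "d": 0}
    n_brackish = 0
    for species in matrix.presence.index:
        habitat = matrix.habitat[species]
        if habitat == "brackish":
            if brackish_policy == "exclude":
                n_brackish += 1
                continue
            habitat = (
                "marine" if brackish_policy == "as_marine" else "freshwater"
            )
        present = bool(matrix.presence.at[species, gene])
        key = ("a" if present else "b") if habitat == "marine" else (
            "c" if present else "d"
        )
        counts[key] += 1
    return ContingencyTable(n_excluded_brackish=n_brackish, **counts)


def concordance_rate(table: ContingencyTable) -> tuple[float, str]:
    """Best habitat-specific concordance and its direction.

    ``marine_retained`` counts marine-present plus freshwater-absent
    species as concordant; ``freshwater_retained`` is the complement.
    The larger rate is returned (ties go to ``marine_retained``), so
    the result is always ≥ 0.5.
    """
    rate_marine = (table.a + table.d) / table.total
    if rate_marine >= 0.5:
        return rate_marine, "marine_retained"
    return 1.0 - rate_marine, "freshwater_retained"


def chi_square_test(
    table: ContingencyTable, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on the 2×2 table (df = 1).

    ``correction=True`` applies the Yates continuity adjustment (the
    default of R's ``chisq.test`` for 2×2 tables).  A table with a zero
    margin has no defined statistic and is returned flagged with
    chi2 = 0, p = 1.
    """
    if table.degenerate:
        return ChiSquareResult(chi2=0.0, df=1, p_value=1.0, degenerate=True)
    chi2, p, df, _ = stats.chi2_contingency(
        table.as_array(), correction=correction
    )
    return ChiSquareResult(chi2=float(chi2), df=int(df), p_value=float(p))


def screen_genes(
    matrix: PresenceMatrix,
    alpha: float = 0.01,
    brackish_policy: BrackishPolicy = "exclude",
    correction: bool = False,
    adjust: Literal["bonferroni", "bh"] | None = None,
) -> list[AssociationResult]:
    """Run the association screen over every gene in the matrix.

    Returns one result per gene, sorted by ascending p-value.  By
    default no multiple-testing adjustment is applied and a gene is
    significant iff its raw p < *alpha*; with ``adjust`` set, the
    adjusted p-values are used for the significance call instead.
    """
    counts = matrix.habitat_counts()
    n_marine = counts["marine"]
    n_fresh = counts["freshwater"]
    if brackish_policy == "as_marine":
        n_marine += counts["brackish"]
    elif brackish_policy == "as_freshwater":
        n_fresh += counts["brackish"]
    if n_marine == 0 or n_fresh == 0:
        raise ValueError(
            "association screen needs both marine and freshwater species "
            f"(after brackish policy {brackish_policy!r}); "
            f"habitat counts: {counts}"
        )

    partial = []
    for gene in matrix.genes:
        tab = contingency_table(matrix, gene, brackish_policy)
        rate, direction = concordance_rate(tab)
        chi = chi_square_test(tab, correction=correction)
        partial.append((gene, tab, rate, direction, chi))

    pvals = np.array([chi.p_value for *_, chi in partial])
    if adjust is None:
        p_adj = [None] * len(partial)
        signif = pvals < alpha
    else:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
        _, adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
        p_adj = list(adj)
        signif = adj < alpha

    results = [
        AssociationResult(
            gene=gene,
            table=tab,
            concordance=rate,
            direction=direction,
            chi2=chi.chi2,
            df=chi.df,
            p_value=chi.p_value,
            significant=bool(sig),
            degenerate=chi.degenerate,
            p_adjusted=adj,
        )
        for (gene, tab, rate, direction, chi), sig, adj in zip(
            partial, signif, p_adj
        )
    ]
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def results_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "marine_present": r.table.a,
                "marine_absent": r.table.b,
                "freshwater_present": r.table.c,
                "freshwater_absent": r.table.d,
                "n_excluded_brackish": r.table.n_excluded_brackish,
                "concordance": r.concordance,
                "direction": r.direction,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[AssociationResult], path: str | Path
) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)
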