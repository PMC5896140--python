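"""Knockout-phenotype contingency tables and the Pearson chi-square test.

Gene-knockout data classify each studied node into one of four male
fertility phenotypes. Cross-tabulating phenotype against node class
(hub vs non-hub) and applying the uncorrected Pearson chi-square test
asks whether removing a hub is more consequential for fertility than
removing an ordinary node. Nodes without knockout data are excluded
before tabulation (they are unstudied, not a fifth phenotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: the four admissible phenotype categories, in display order
CATEGORIES: tuple[str, ...] = (
    "male infertile",
    "male hypofertile",
    "male fertility affected",
    "male fertility unaffected/normal phenotype",
)

CLASSES: tuple[str, str] = ("hub", "non-hub")


class CategoryError(ValueError):
    """An annotation uses a label outside the admissible category set."""


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PhenotypeTable:
    """Phenotype-by-class counts with per-column percentages.

    ``counts`` is indexed by the four categories with one column per node
    class; ``percentages`` divides by the column totals and rounds
    half-up to one decimal.
    """

    counts: pd.DataFrame

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        pct = self.counts.astype(float).copy()
        for col in pct.columns:
            tot = totals[col]
            pct[col] = (
                [_round1(100.0 * v / tot) for v in self.counts[col]]
                if tot > 0
                else 0.0
            )
        return pct

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_table(
    annotations: Mapping[str, str], hubs: Iterable[str]
) -> PhenotypeTable:
    """Cross-tabulate phenotype category against hub membership.

    ``annotations`` maps node -> category for the studied nodes only;
    any node absent from it is simply not tabulated. Unknown category
    labels raise :class:`CategoryError` naming the offenders.
    """
    hub_set = set(hubs)
    bad = sorted({c for c in annotations.values() if c not in CATEGORIES})
    if bad:
        raise CategoryError(f"unknown phenotype categories: {bad}")
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CLASSES))
    for node, cat in annotations.items():
        cls = "hub" if node in hub_set else "non-hub"
        counts.loc[cat, cls] += 1
    if counts.to_numpy().sum() == 0:
        warnings.warn("no annotated nodes: all-zero phenotype table", stacklevel=2)
    return PhenotypeTable(counts=counts)


@dataclass
class ContingencyResult:
    """Uncorrected Pearson chi-square on an r x c table."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float


def chi_square(table: PhenotypeTable | pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    The expected counts come from the row/column margins; the p-value is
    the chi-square survival function at df = (r-1)(c-1). A warning is
    emitted when the smallest expected count falls below 5 (the usual
    validity caveat).
    """
    if isinstance(table, PhenotypeTable):
        obs = table.counts.to_numpy()
    elif isinstance(table, pd.DataFrame):
        obs = table.to_numpy()
    else:
        obs = np.asarray(table)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: test undefined")
    statistic, p, df, expected = stats.chi2_contingency(obs, correction=False)
    min_exp = float(expected.min())
    if min_exp < 5:
        warnings.warn(
            f"minimum expected count {min_exp:.2f} < 5: chi-square approximation "
            "may be unreliable",
            stacklevel=2,
        )
    return ContingencyResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        expected=expected,
        min_expected=min_exp,
    )
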