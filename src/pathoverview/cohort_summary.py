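"""Immunophenotype table summarisation and cohort count statistics.

The quantitative half of the package: a machine-readable per-xenograft
phenotype table (marker calls, immunoglobulin light-chain pattern, EBER
status for each B-cell lymphoproliferation arising in a lung-cancer PDX
program) plus the aggregate cohort counts, with the derived summaries a
pathology report quotes — per-stain call counts, kappa/lambda restriction
categories, formatted percentages, and two-group Pearson chi-square tests.

Marker calls use a closed vocabulary: ``+`` positive, ``-`` negative, ``#``
focal/partial positivity (kept as its own category, never folded into ``+``
or ``-``), and ``unavailable``.  The light-chain code is ``K`` or ``L`` for
a restricted population, with a parenthesised second chain (``K (L)``,
``L (K)``) marking dual expression.  A row whose histology sample was
unavailable carries ``unavailable`` in every call column and is excluded
from the evaluable denominator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

from .wsi_core import ParameterError, PathOverviewError

logger = logging.getLogger("pathoverview")

__all__ = [
    "STAIN_COLUMNS",
    "MARKER_CALLS",
    "IG_CODES",
    "TableParseError",
    "DegenerateTableError",
    "PhenotypeTable",
    "SummaryCounts",
    "TestResult",
    "load_phenotype_table",
    "bundled_phenotype_table",
    "load_cohort_counts",
    "classify_ig",
    "count_categories",
    "proportion_pct",
    "two_proportion_chi2",
    "mann_whitney",
    "kruskal_wallis",
    "summarize",
]

#: stain columns in printed order
STAIN_COLUMNS: tuple[str, ...] = (
    "CD20", "CD79A", "CD3", "BCL2", "CD56", "CD10",
    "BCL6", "MUM1", "CD138", "CD30", "EBER",
)
MARKER_CALLS = frozenset({"+", "-", "#", "unavailable"})
IG_CODES = frozenset({"K", "L", "K (L)", "L (K)", "unavailable"})


class TableParseError(PathOverviewError):
    """Phenotype CSV violates the schema or call vocabulary."""


class DegenerateTableError(PathOverviewError):
    """A contingency table has a zero margin; the test is undefined."""


@dataclass
class PhenotypeTable:
    """Validated per-xenograft phenotype calls, stain order as printed."""

    df: pd.DataFrame

    @property
    def rows(self) -> list[dict]:
        out = []
        for _, r in self.df.iterrows():
            out.append(
                {
                    "patient": r["patient"],
                    "region": r["region"],
                    "markers": {s: r[s] for s in STAIN_COLUMNS},
                    "ig": r["ig"],
                }
            )
        return out

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SummaryCounts:
    per_stain: dict[str, dict[str, int]]
    ig_counts: dict[str, int]
    eber_positive: int
    evaluable: int
    n_rows: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str = "pearson-chi-square"

    @property
    def significant_at_0_05(self) -> bool:
        return self.p_value < 0.05


def load_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Load and validate a phenotype CSV (header: patient,region,<stains>,ig).

    Unknown call tokens are rejected with an error naming the offending row
    and column — silent coercion of a pathology call is never acceptable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TableParseError(f"{path}: not a parseable CSV: {exc}") from exc
    expected = ["patient", "region", *STAIN_COLUMNS, "ig"]
    if list(df.columns) != expected:
        raise TableParseError(
            f"{path}: header must be {','.join(expected)}, got "
            f"{','.join(df.columns)}"
        )
    if len(df) == 0:
        raise TableParseError(f"{path}: table has no data rows")
    df = df.fillna("")
    for idx, row in df.iterrows():
        for col in STAIN_COLUMNS:
            if row[col] not in MARKER_CALLS:
                raise TableParseError(
                    f"{path}: row {idx + 1} ({row['patient']} {row['region']}), "
                    f"column {col}: invalid call {row[col]!r}"
                )
        if row["ig"] not in IG_CODES:
            raise TableParseError(
                f"{path}: row {idx + 1} ({row['patient']} {row['region']}), "
                f"column ig: invalid code {row['ig']!r}"
            )
    return PhenotypeTable(df)


def bundled_phenotype_table() -> PhenotypeTable:
    """The phenotype table bundled with the package (16 xenograft rows)."""
    ref = resources.files("pathoverview").joinpath("data/table1_phenotypes.csv")
    with resources.as_file(ref) as p:
        return load_phenotype_table(p)


def load_cohort_counts() -> dict:
    """Bundled aggregate cohort counts (numerator/denominator pairs)."""
    ref = resources.files("pathoverview").joinpath("data/cohort_counts.json")
    return json.loads(ref.read_text())


def classify_ig(code: str) -> str:
    """Light-chain pattern category for one Ig code.

    ``K`` → kappa_only, ``L`` → lambda_only; any parenthesised second chain
    means a dual-expressing population regardless of which chain dominates.
    """
    if code not in IG_CODES:
        raise ParameterError(f"unknown ig code {code!r}")
    if code == "unavailable":
        return "unavailable"
    if "(" in code:
        return "dual"
    return "kappa_only" if code == "K" else "lambda_only"


def count_categories(table: PhenotypeTable) -> SummaryCounts:
    """Per-stain call counts, light-chain categories, EBER and evaluable n."""
    df = table.df
    per_stain = {
        stain: {
            call: int((df[stain] == call).sum())
            for call in sorted(MARKER_CALLS)
        }
        for stain in STAIN_COLUMNS
    }
    ig_counts = {
        "kappa_only": 0, "lambda_only": 0, "dual": 0, "unavailable": 0,
    }
    for code in df["ig"]:
        ig_counts[classify_ig(code)] += 1
    unavailable_rows = int(
        (df[list(STAIN_COLUMNS)] == "unavailable").all(axis=1).sum()
    )
    return SummaryCounts(
        per_stain=per_stain,
        ig_counts=ig_counts,
        eber_positive=per_stain["EBER"]["+"],
        evaluable=len(df) - unavailable_rows,
        n_rows=len(df),
    )


def proportion_pct(k: int, n: int) -> str:
    """``k/n`` as a percentage with one decimal, round half away from zero."""
    if n <= 0:
        raise ParameterError(f"denominator must be > 0, got {n}")
    if not (0 <= k <= n):
        raise ParameterError(f"need 0 <= k <= n, got k={k}, n={n}")
    pct = (Decimal(k) * 100 / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


def two_proportion_chi2(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Compares the proportions ``k1/n1`` vs ``k2/n2`` two-sided; p is the
    chi-square upper tail.  A zero margin (all successes or all failures
    pooled) leaves the test undefined and raises
    :class:`DegenerateTableError`.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise ParameterError(f"invalid counts k={k}, n={n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        raise DegenerateTableError(
            f"table {table} has a zero column margin; chi-square undefined"
        )
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U on user-supplied per-sample values.

    Exposed for latency-style comparisons; the bundled data carries no
    per-sample day vectors (only medians are published), so no fixture
    accompanies this operation.
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="mann-whitney-u",
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H over user-supplied groups (see mann_whitney note)."""
    res = stats.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="kruskal-wallis",
    )


def summarize(
    table: PhenotypeTable, cohort_counts: dict | None = None
) -> dict:
    """Full summary dict (counts, formatted proportions, chi-square tests).

    ``cohort_counts`` maps names to ``{"k": int, "n": int}``; comparison
    pairs listed under ``"comparisons"`` as two-name pairs are tested with
    the Pearson chi-square.  Defaults to the bundled cohort counts.
    """
    if cohort_counts is None:
        cohort_counts = load_cohort_counts()
    counts = count_categories(table)
    out: dict = {
        "n_rows": counts.n_rows,
        "evaluable": counts.evaluable,
        "eber_positive": counts.eber_positive,
        "ig_counts": counts.ig_counts,
        "per_stain": counts.per_stain,
        "proportions": {},
        "tests": {},
        "test_settings": {
            "method": "pearson-chi-square",
            "continuity_correction": False,
            "alpha": 0.05,
        },
    }
    groups = cohort_counts.get("groups", {})
    for name, kn in groups.items():
        out["proportions"][name] = {
            "k": kn["k"],
            "n": kn["n"],
            "pct": proportion_pct(kn["k"], kn["n"]),
        }
    for a, b in cohort_counts.get("comparisons", []):
        ka, na = groups[a]["k"], groups[a]["n"]
        kb, nb = groups[b]["k"], groups[b]["n"]
        t = two_proportion_chi2(ka, na, kb, nb)
        out["tests"][f"{a}_vs_{b}"] = {
            "statistic": t.statistic,
            "p_value": t.p_value,
            "significant_at_0_05": t.significant_at_0_05,
        }
    return out
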