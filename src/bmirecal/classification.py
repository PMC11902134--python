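"""Adiposity classification and agreement statistics.

Subjects are classified by DXA body-fat percentage (reference bands) or by
BMI (WHO or recalibrated cut-offs); agreement between two classification
systems is summarised by a contingency table with unweighted Cohen's kappa,
the Pearson chi-squared test of independence (no continuity correction) and
capture / false-positive rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, DomainError

__all__ = [
    "WeightCategory",
    "CutoffSet",
    "BfBands",
    "ContingencyResult",
    "WHO_CUTOFFS",
    "classify_bf",
    "classify_bmi",
    "cross_tabulate",
    "cohen_kappa",
    "chi_squared_independence",
    "agreement_rates",
    "kappa_label",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report convention), e.g. 24.85 -> 24.9."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class WeightCategory(str, Enum):
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY = "obesity"
    #: collapsed positive class used in the 2x2 agreement tables
    OVERWEIGHT_OR_OBESITY = "overweight_or_obesity"

    def collapsed(self) -> "WeightCategory":
        if self is WeightCategory.NORMAL:
            return WeightCategory.NORMAL
        return WeightCategory.OVERWEIGHT_OR_OBESITY


THREE_CLASS = (WeightCategory.NORMAL, WeightCategory.OVERWEIGHT, WeightCategory.OBESITY)
TWO_CLASS = (WeightCategory.NORMAL, WeightCategory.OVERWEIGHT_OR_OBESITY)


@dataclass(frozen=True)
class CutoffSet:
    """Named BMI thresholds; thresholds are inclusive upward (">=")."""

    name: str
    overweight_bmi: float
    obesity_bmi: float
    provenance: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.overweight_bmi < self.obesity_bmi):
            raise DomainError(
                f"need 0 < overweight_bmi < obesity_bmi, got "
                f"({self.overweight_bmi}, {self.obesity_bmi})"
            )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "overweight_bmi": self.overweight_bmi,
            "obesity_bmi": self.obesity_bmi,
        }
        if self.provenance is not None:
            d["provenance"] = self.provenance
        return d


WHO_CUTOFFS = CutoffSet("WHO", 25.0, 30.0)


@dataclass(frozen=True)
class BfBands:
    """Reference body-fat bands for young adult males (inclusive upward)."""

    overweight_bf: float = 21.0
    obesity_bf: float = 26.0

    def __post_init__(self) -> None:
        if not (0 < self.overweight_bf < self.obesity_bf < 100):
            raise DomainError(
                f"need 0 < overweight_bf < obesity_bf < 100, got "
                f"({self.overweight_bf}, {self.obesity_bf})"
            )


def classify_bf(bf_pct: float, bands: BfBands = BfBands()) -> WeightCategory:
    """Classify a body-fat percentage into the three adiposity categories."""
    if not (0 < bf_pct < 100):
        raise DomainError(f"bf_pct must lie in (0, 100), got {bf_pct}")
    if bf_pct >= bands.obesity_bf:
        return WeightCategory.OBESITY
    if bf_pct >= bands.overweight_bf:
        return WeightCategory.OVERWEIGHT
    return WeightCategory.NORMAL


def classify_bmi(bmi: float, cutoffs: CutoffSet = WHO_CUTOFFS) -> WeightCategory:
    """Classify a BMI into the three weight-status categories."""
    if not bmi > 0:
        raise DomainError(f"bmi must be positive, got {bmi}")
    if bmi >= cutoffs.obesity_bmi:
        return WeightCategory.OBESITY
    if bmi >= cutoffs.overweight_bmi:
        return WeightCategory.OVERWEIGHT
    return WeightCategory.NORMAL


def classify_bf_many(bf_pct: Sequence[float], bands: BfBands = BfBands()) -> list[WeightCategory]:
    return [classify_bf(float(v), bands) for v in bf_pct]


def classify_bmi_many(bmi: Sequence[float], cutoffs: CutoffSet = WHO_CUTOFFS) -> list[WeightCategory]:
    return [classify_bmi(float(v), cutoffs) for v in bmi]


@dataclass(frozen=True)
class ContingencyResult:
    """Cross-tabulation of two classifiers plus agreement statistics.

    Rows index the first (BMI-based) classifier, columns the second
    (body-fat reference). Rates are computed on the collapsed 2x2 counts
    regardless of table size; chi-squared fields are ``None`` when the
    table is degenerate (a zero expected count).
    """

    table: np.ndarray
    n: int
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    kappa: float
    kappa_label: str
    observed_agreement: float
    expected_agreement: float
    chi2: float | None
    chi2_df: int | None
    chi2_p: float | None
    capture_rate: float | None
    false_positive_rate: float | None

    def as_report_dict(self) -> dict:
        """JSON-friendly summary with report rounding (kappa 3 d.p., rates 1 d.p.)."""
        rnd = lambda v, d: None if v is None or math.isnan(v) else round_half_up(v, d)
        return {
            "table": self.table.tolist(),
            "n": self.n,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "kappa": rnd(self.kappa, 3),
            "kappa_label": self.kappa_label,
            "observed_agreement": rnd(self.observed_agreement, 4),
            "expected_agreement": rnd(self.expected_agreement, 4),
            "chi2": rnd(self.chi2, 3),
            "chi2_df": self.chi2_df,
            "chi2_p": None if self.chi2_p is None else float(self.chi2_p),
            "capture_rate": rnd(self.capture_rate, 1),
            "false_positive_rate": rnd(self.false_positive_rate, 1),
        }


def _as_table(table: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise DegenerateTableError(f"table must be 2-D, got shape {t.shape}")
    if (t < 0).any():
        raise DegenerateTableError("table contains negative counts")
    return t


def cohen_kappa(table: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Unweighted Cohen's kappa, (Po - Pe) / (1 - Pe).

    Returns ``nan`` (undefined) when chance agreement Pe equals 1.
    """
    t = _as_table(table)
    if t.shape[0] != t.shape[1]:
        raise DegenerateTableError(f"kappa needs a square table, got {t.shape}")
    n = t.sum()
    if n <= 0:
        raise DegenerateTableError("kappa undefined for an all-zero table")
    po = np.trace(t) / n
    pe = float(t.sum(axis=1) @ t.sum(axis=0)) / n**2
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return math.nan
    return float((po - pe) / (1.0 - pe))


def chi_squared_independence(
    table: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    t = _as_table(table)
    n = t.sum()
    if n <= 0:
        raise DegenerateTableError("chi-squared undefined for an all-zero table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected <= 0).any():
        raise DegenerateTableError("zero expected count: a marginal total is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def agreement_rates(table: Sequence[Sequence[float]] | np.ndarray) -> tuple[float | None, float | None]:
    """Capture and false-positive rates (%) of a 2x2 table.

    Columns are the reference classifier (col 0 = normal, col 1 = positive);
    rows are the index classifier. capture = positives called positive /
    reference positives; false-positive = normals called positive /
    reference normals. A zero column total yields ``None`` for that rate.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise DegenerateTableError(f"rates need a 2x2 table, got {t.shape}")
    col_normal, col_positive = t.sum(axis=0)
    capture = None if col_positive == 0 else float(t[1, 1] / col_positive * 100.0)
    false_pos = None if col_normal == 0 else float(t[1, 0] / col_normal * 100.0)
    return capture, false_pos


_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_label(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value in [-1, 1]."""
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 <= kappa <= 1.0:
        raise DomainError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"  # pragma: no cover


def _collapse_counts(t: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    """Merge all non-normal rows/columns into a single positive class."""
    normal = labels.index(WeightCategory.NORMAL.value)
    keep = np.arange(t.shape[0]) != normal
    out = np.empty((2, 2), dtype=t.dtype)
    out[0, 0] = t[normal, normal]
    out[0, 1] = t[normal, keep].sum()
    out[1, 0] = t[keep, normal].sum()
    out[1, 1] = t[np.ix_(keep, keep)].sum()
    return out


def cross_tabulate(
    categories_a: Sequence[WeightCategory],
    categories_b: Sequence[WeightCategory],
    collapse: bool = False,
) -> ContingencyResult:
    """Cross-tabulate two paired category sequences and attach statistics.

    ``categories_a`` indexes the rows (BMI classifier), ``categories_b`` the
    columns (body-fat reference). With ``collapse`` the overweight and
    obesity classes merge into one positive class before tabulation.
    """
    if len(categories_a) != len(categories_b):
        raise DomainError(
            f"paired sequences differ in length: {len(categories_a)} vs {len(categories_b)}"
        )
    if len(categories_a) == 0:
        raise DomainError("empty category sequences")

    if collapse:
        cats = TWO_CLASS
        a = [WeightCategory(c).collapsed() for c in categories_a]
        b = [WeightCategory(c).collapsed() for c in categories_b]
    else:
        cats = THREE_CLASS
        a = [WeightCategory(c) for c in categories_a]
        b = [WeightCategory(c) for c in categories_b]
        if any(c is WeightCategory.OVERWEIGHT_OR_OBESITY for c in a + b):
            raise DomainError("collapsed labels require collapse=True")

    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for ca, cb in zip(a, b):
        table[index[ca], index[cb]] += 1

    labels = tuple(c.value for c in cats)
    n = int(table.sum())
    kappa = cohen_kappa(table)
    po = float(np.trace(table) / n)
    pe = float(table.sum(axis=1) @ table.sum(axis=0)) / n**2
    try:
        chi2, df, p = chi_squared_independence(table)
    except DegenerateTableError:
        chi2, df, p = None, None, None

    two_by_two = table if table.shape == (2, 2) else _collapse_counts(table, labels)
    capture, false_pos = agreement_rates(two_by_two)

    return ContingencyResult(
        table=table,
        n=n,
        row_labels=labels,
        col_labels=labels,
        kappa=kappa,
        kappa_label=kappa_label(kappa) if not math.isnan(kappa) else "undefined",
        observed_agreement=po,
        expected_agreement=pe,
        chi2=chi2,
        chi2_df=df,
        chi2_p=p,
        capture_rate=capture,
        false_positive_rate=false_pos,
    )
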