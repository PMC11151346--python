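"""Accuracy study machinery: review categories, agreement, κ, and metrics.

The grouping algorithm is judged per diagnosis against clinician review.
Each reviewed item is placed in one of four assessment categories:

* **TP** — assigned to a system grouper, and it is the right system;
* **FP** — assigned to a system grouper, but the wrong one;
* **TN** — left in "Other", and the concept really is too unspecific to
  attribute to any system;
* **FN** — left in "Other" although it belongs to a system (a logic deficit
  in the groupers).

Two raters categorize independently; discordant items are resolved either by
discussion (modeled as revised rater columns) or by a third-rater tie-break
— only true tie-breaks count as adjudications. The resolved categories feed
a confusion matrix, from which sensitivity, specificity, PPV, NPV and F1 are
derived; inter-rater reliability is unweighted Cohen κ over the four
categories.

Percentages are rendered half-away-from-zero to one decimal (F1 to three),
computed in exact rational arithmetic so boundary cases like 14.25 → 14.3
never depend on binary floating point.

``reconstruct_counts`` inverts the rendering: given a study's total, its TN
count and its printed (rounded) sensitivity and PPV, it exhaustively searches
for the integer confusion matrices consistent with them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import EvaluationError, ReconstructionError
from .groupers import OTHER_NAME


class AssessmentCategory(str, Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"


CATEGORIES = tuple(AssessmentCategory)


# ---------------------------------------------------------------------------
# exact half-away-from-zero rendering


def _round_half_away(value: Fraction, ndigits: int) -> Fraction:
    scale = Fraction(10) ** ndigits
    scaled = value * scale
    if scaled >= 0:
        q = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
    else:
        q = -((-2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator))
    return Fraction(q, 1) / scale


def render_ratio(numerator: int, denominator: int, ndigits: int = 1,
                 percent: bool = True) -> float:
    """Exact rendering of a ratio: half-away-from-zero at ``ndigits``."""
    if denominator == 0:
        raise EvaluationError("cannot render a ratio with zero denominator")
    frac = Fraction(numerator, denominator) * (100 if percent else 1)
    return float(_round_half_away(frac, ndigits))


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Half-away-from-zero rounding of a float (via its shortest repr)."""
    return float(_round_half_away(Fraction(Decimal(repr(value))), ndigits))


# ---------------------------------------------------------------------------
# categorization


def categorize(
    assigned_grouper: str,
    gold_grouper: str,
    valid_groupers: Iterable[str] | None = None,
) -> AssessmentCategory:
    """Table of truth for one reviewed item (see module docstring).

    ``valid_groupers`` optionally restricts the admissible system names
    ("Other" is always admissible); an unknown name is a hard error.
    """
    if valid_groupers is not None:
        valid = set(valid_groupers) | {OTHER_NAME}
        for name in (assigned_grouper, gold_grouper):
            if name not in valid:
                raise EvaluationError(f"unknown grouper name {name!r}")
    if not assigned_grouper or not gold_grouper:
        raise EvaluationError("grouper names must be nonempty")
    if assigned_grouper != OTHER_NAME:
        return (
            AssessmentCategory.TP
            if assigned_grouper == gold_grouper
            else AssessmentCategory.FP
        )
    return (
        AssessmentCategory.TN if gold_grouper == OTHER_NAME else AssessmentCategory.FN
    )


# ---------------------------------------------------------------------------
# review records and adjudication


@dataclass(frozen=True)
class ReviewRecord:
    """One item's dual review, with optional third-rater tie-break."""

    entry_id: str
    rater_a: AssessmentCategory
    rater_b: AssessmentCategory
    adjudicated: AssessmentCategory | None = None

    @property
    def concordant(self) -> bool:
        return self.rater_a == self.rater_b

    @property
    def final(self) -> AssessmentCategory:
        if self.concordant:
            return self.rater_a
        if self.adjudicated is None:
            raise EvaluationError(
                f"record {self.entry_id!r} is discordant and unadjudicated"
            )
        return self.adjudicated


@dataclass(frozen=True)
class AdjudicationResult:
    records: tuple[ReviewRecord, ...]
    n_adjudicated: int


def adjudicate(
    records: Sequence[ReviewRecord],
    tiebreak_source: Mapping[str, AssessmentCategory],
) -> AdjudicationResult:
    """Resolve discordant records from a per-entry tie-break table.

    Concordant records pass through untouched; each discordant record takes
    the tie-break category and counts toward ``n_adjudicated``. A discordant
    record with no tie-break is a hard error.
    """
    out: list[ReviewRecord] = []
    n = 0
    for rec in records:
        if rec.concordant:
            out.append(rec)
            continue
        if rec.adjudicated is not None:
            out.append(rec)
            n += 1
            continue
        if rec.entry_id not in tiebreak_source:
            raise EvaluationError(f"no tie-break for discordant record {rec.entry_id!r}")
        out.append(replace(rec, adjudicated=tiebreak_source[rec.entry_id]))
        n += 1
    return AdjudicationResult(tuple(out), n)


# ---------------------------------------------------------------------------
# counts and metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def tally(finals: Iterable[AssessmentCategory | ReviewRecord]) -> ConfusionCounts:
    """Count resolved categories (accepts categories or resolved records)."""
    counts = {c: 0 for c in CATEGORIES}
    for item in finals:
        cat = item.final if isinstance(item, ReviewRecord) else item
        counts[AssessmentCategory(cat)] += 1
    return ConfusionCounts(
        tp=counts[AssessmentCategory.TP],
        fp=counts[AssessmentCategory.FP],
        tn=counts[AssessmentCategory.TN],
        fn=counts[AssessmentCategory.FN],
    )


@dataclass(frozen=True)
class Metrics:
    """Full-precision derived metrics; ``None`` marks an undefined value
    (zero denominator), never a silent 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return Metrics(
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
    )


def render_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Printed-precision metrics: percentages at 1 decimal, F1 at 3, both
    half-away-from-zero in exact arithmetic."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def pct(num: int, den: int) -> float | None:
        return render_ratio(num, den) if den else None

    f1 = (
        render_ratio(2 * tp, 2 * tp + fp + fn, ndigits=3, percent=False)
        if (2 * tp + fp + fn)
        else None
    )
    return {
        "sensitivity_pct": pct(tp, tp + fn),
        "specificity_pct": pct(tn, tn + fp),
        "ppv_pct": pct(tp, tp + fp),
        "npv_pct": pct(tn, tn + fn),
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# agreement and kappa


@dataclass(frozen=True)
class AgreementResult:
    n_concordant: int
    n_total: int

    @property
    def proportion(self) -> float:
        return self.n_concordant / self.n_total


def agreement(
    rater_a: Sequence[AssessmentCategory], rater_b: Sequence[AssessmentCategory]
) -> AgreementResult:
    """Raw concordance between two equal-length rating vectors."""
    if len(rater_a) != len(rater_b):
        raise EvaluationError("rater vectors differ in length")
    if not rater_a:
        raise EvaluationError("rater vectors are empty")
    n = sum(a == b for a, b in zip(rater_a, rater_b))
    return AgreementResult(n, len(rater_a))


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float


def cohen_kappa(
    rater_a: Sequence[AssessmentCategory], rater_b: Sequence[AssessmentCategory]
) -> KappaResult:
    """Unweighted Cohen κ over the four assessment categories.

    κ = (p_o − p_e) / (1 − p_e) with p_e from the raters' marginal category
    frequencies; when both raters are constant and identical (p_o = p_e = 1)
    κ is 1 by convention.
    """
    if len(rater_a) != len(rater_b):
        raise EvaluationError("rater vectors differ in length")
    n = len(rater_a)
    if n == 0:
        raise EvaluationError("rater vectors are empty")
    po = Fraction(sum(a == b for a, b in zip(rater_a, rater_b)), n)
    pe = Fraction(0)
    for cat in CATEGORIES:
        pe += Fraction(sum(a == cat for a in rater_a), n) * Fraction(
            sum(b == cat for b in rater_b), n
        )
    if pe == 1:
        return KappaResult(float(po), 1.0, 1.0 if po == 1 else 0.0)
    kappa = (po - pe) / (1 - pe)
    return KappaResult(float(po), float(pe), float(kappa))


# ---------------------------------------------------------------------------
# confusion-matrix reconstruction from printed marginals


@dataclass(frozen=True)
class ReconstructionResult:
    solutions: tuple[ConfusionCounts, ...]
    unique: bool

    @property
    def counts(self) -> ConfusionCounts:
        return self.solutions[0]


def _tenths(pct: float) -> int:
    """A printed 1-decimal percentage as an exact integer number of tenths."""
    d = Decimal(repr(pct)).scaleb(1)
    if d != d.to_integral_value():
        raise EvaluationError(f"{pct!r} is not a 1-decimal percentage")
    return int(d)


def _rounds_to_tenths(num: int, den: int, tenths: int) -> bool:
    # 100*num/den rounds (half-away-from-zero, 1 decimal) to tenths/10
    # <=> tenths <= 1000*num/den + 1/2 < tenths + 1, in integers:
    return den * (2 * tenths - 1) <= 2000 * num < den * (2 * tenths + 1)


def reconstruct_counts(
    n_total: int,
    tn: int,
    sensitivity_pct: float,
    ppv_pct: float,
) -> ReconstructionResult:
    """Find all integer (tp, fp, fn) with tp+fp+fn = n_total − tn whose
    sensitivity and PPV round to the stated 1-decimal percentages.

    Raises :class:`ReconstructionError` if no matrix is consistent; the
    ``unique`` flag is False when several are.
    """
    if not n_total > tn >= 0:
        raise EvaluationError("require n_total > tn >= 0")
    sens_t = _tenths(sensitivity_pct)
    ppv_t = _tenths(ppv_pct)
    pos = n_total - tn
    sols: list[ConfusionCounts] = []
    for tp in range(pos + 1):
        for fn in range(pos - tp + 1):
            fp = pos - tp - fn
            if tp + fn == 0 or tp + fp == 0:
                continue  # the stated percentage implies a defined ratio
            if _rounds_to_tenths(tp, tp + fn, sens_t) and _rounds_to_tenths(
                tp, tp + fp, ppv_t
            ):
                sols.append(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    if not sols:
        raise ReconstructionError(
            f"no confusion matrix with N={n_total}, TN={tn} yields "
            f"sensitivity {sensitivity_pct}% and PPV {ppv_pct}%"
        )
    return ReconstructionResult(tuple(sols), len(sols) == 1)
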