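"""Assessment statistics for report-level phenotyping and entity agreement.

Per phenotype the evaluation is a 2x2 report-level confusion table from
which sensitivity (recall), specificity and positive predictive value
(precision) are reported with 95% Wilson score intervals; the Wilson method
is used because estimates sit near 0% or 100%, where Wald intervals
misbehave.  F1 is the harmonic mean of PPV and sensitivity.  Cohen's kappa
measures chance-corrected agreement on document labels between two
annotators, and precision/recall/F1 measure entity-level agreement.  The
sample-size planner inverts the Wilson interval width: the smallest positive
case count whose interval is narrow enough, divided by the expected
prevalence.

Metrics with empty denominators are reported as *undefined* (estimate
``None``), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import norm

from .phenotype_labelling import LabelledReport, Phenotype


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricResult:
    name: str  # sensitivity | specificity | ppv | f1 | kappa
    estimate: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    numerator: Optional[int] = None
    denominator: Optional[int] = None

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    def format(self, dp: int = 2) -> str:
        if self.estimate is None:
            return "-"
        s = f"{self.estimate:.{dp}f}"
        if self.ci_low is not None:
            s += f" ({self.ci_low:.{dp}f}-{self.ci_high:.{dp}f})"
        return s


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for *k* successes in *n* trials.

    Asymmetric and well-behaved at proportions near 0 or 1, unlike the Wald
    interval.  Raises :class:`UndefinedMetricError` for ``n == 0``.
    """
    if n == 0:
        raise UndefinedMetricError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = _wilson_bounds(k / n, n, confidence)
    # the score interval closes exactly at 0 and 1 for degenerate counts
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return lo, hi


def _wilson_bounds(phat: float, n: float, confidence: float) -> tuple[float, float]:
    z = norm.ppf(1 - (1 - confidence) / 2)
    z2 = z * z
    denom = 1 + z2 / n
    centre = (phat + z2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z2 / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def wilson_width(phat: float, n: float, confidence: float = 0.95) -> float:
    lo, hi = _wilson_bounds(phat, n, confidence)
    return hi - lo


def confusion_counts(
    pred: Sequence[LabelledReport],
    gold: Sequence[LabelledReport],
    phenotype: Phenotype | Iterable[Phenotype],
) -> ConfusionCounts:
    """Report-level confusion table for one phenotype (or, for aggregate
    rows like "any ischaemic stroke", any of a set of phenotypes)."""
    pred_ids = {r.report_id for r in pred}
    gold_ids = {r.report_id for r in gold}
    if pred_ids != gold_ids:
        missing = sorted(pred_ids ^ gold_ids)
        raise ValueError(f"pred/gold report sets differ; unmatched ids: {missing}")
    targets = {phenotype} if isinstance(phenotype, Phenotype) else set(phenotype)
    gold_by_id = {r.report_id: r for r in gold}
    tp = fp = fn = tn = 0
    for p in pred:
        g = gold_by_id[p.report_id]
        in_pred = bool(targets & p.labels)
        in_gold = bool(targets & g.labels)
        if in_pred and in_gold:
            tp += 1
        elif in_pred:
            fp += 1
        elif in_gold:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def _proportion_metric(name: str, k: int, n: int, confidence: float) -> MetricResult:
    if n == 0:
        return MetricResult(name, None, numerator=k, denominator=n)
    lo, hi = wilson_ci(k, n, confidence)
    return MetricResult(name, k / n, lo, hi, k, n)


def report_metrics(counts: ConfusionCounts, confidence: float = 0.95) -> list[MetricResult]:
    """Sensitivity, specificity and PPV (each with Wilson CI) plus F1."""
    sens = _proportion_metric("sensitivity", counts.tp, counts.tp + counts.fn, confidence)
    spec = _proportion_metric("specificity", counts.tn, counts.tn + counts.fp, confidence)
    ppv = _proportion_metric("ppv", counts.tp, counts.tp + counts.fp, confidence)
    f1 = MetricResult("f1", f1_score(sens.estimate, ppv.estimate))
    return [sens, spec, ppv, f1]


def f1_score(recall: Optional[float], precision: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and recall; undefined if either is."""
    if recall is None or precision is None:
        return None
    if recall + precision == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def cohens_kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> float:
    """Chance-corrected agreement between two per-report boolean vectors.

    Expected agreement uses the product of marginals; perfect observed
    agreement with degenerate marginals (both annotators constant) is 1.
    """
    if len(labels_a) != len(labels_b) or not labels_a:
        raise ValueError("need two equal-length, non-empty label vectors")
    n = len(labels_a)
    a = [bool(x) for x in labels_a]
    b = [bool(x) for x in labels_b]
    po = sum(x == y for x, y in zip(a, b)) / n
    pa, pb = sum(a) / n, sum(b) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def entity_prf(
    gold: Sequence,
    pred: Sequence,
    matching: str = "exact",
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Entity-level precision/recall/F1 between two annotation sets.

    ``exact`` requires identical span and type; ``overlap`` requires span
    intersection and the same type.  Greedy left-to-right matching; each gold
    entity is matched at most once.  Accepts pipeline entities or standoff
    entities (anything with ``span`` and a type).
    """
    if matching not in ("exact", "overlap"):
        raise ValueError(f"unknown matching mode {matching!r}")

    def key(e):
        if hasattr(e, "etype"):
            from .types import entity_type_to_string
            t = entity_type_to_string(e.etype, getattr(e, "subtype", None))
        else:
            t = e.type
        return t, e.span

    gold_items = sorted((key(e) for e in gold), key=lambda x: (x[1].start, x[1].end))
    pred_items = sorted((key(e) for e in pred), key=lambda x: (x[1].start, x[1].end))
    matched_gold = [False] * len(gold_items)
    tp = 0
    for pt, pspan in pred_items:
        for gi, (gt, gspan) in enumerate(gold_items):
            if matched_gold[gi] or gt != pt:
                continue
            ok = gspan == pspan if matching == "exact" else gspan.overlaps(pspan)
            if ok:
                matched_gold[gi] = True
                tp += 1
                break
    precision = tp / len(pred_items) if pred_items else None
    recall = tp / len(gold_items) if gold_items else None
    return precision, recall, f1_score(recall, precision)


def min_sample_size(
    p: float,
    prevalence: float,
    max_width: float,
    round_to: Optional[int] = None,
    confidence: float = 0.95,
    max_cases: int = 10_000_000,
) -> int:
    """Reports needed so the Wilson interval around an observed proportion
    *p* among positives has total width at most *max_width*.

    Searches for the smallest positive-case count ``m`` with
    ``wilson_width(p, m) <= max_width``, then scales by the phenotype
    prevalence (``n = ceil(m / prevalence)``), optionally rounding up to a
    granularity such as the nearest hundred.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    if max_width <= 0:
        raise ValueError("max_width must be positive")
    # width is strictly decreasing in m, so bracket by doubling then bisect
    hi = 1
    while hi <= max_cases and wilson_width(p, hi, confidence) > max_width:
        hi *= 2
    if hi > max_cases:
        raise ValueError(f"width {max_width} unattainable within {max_cases} cases")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if wilson_width(p, mid, confidence) <= max_width:
            hi = mid
        else:
            lo = mid
    m = hi if wilson_width(p, 1, confidence) > max_width else 1
    n = math.ceil(m / prevalence)
    if round_to:
        n = math.ceil(n / round_to) * round_to
    return n
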