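"""Diagnostic-accuracy statistics: confusion tables, metrics, confidence intervals.

A marker (or combination rule) is compared against reference HLA typing as a
binary diagnostic test for carrier status:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)

Sensitivity/specificity intervals default to the exact Clopper–Pearson
(beta-quantile) interval; its x=n lower bound has the closed form
(alpha/2)**(1/n).  Predictive-value intervals default to the adjusted logit
interval (normal interval on log((x+0.5)/(n-x+0.5)) back-transformed), which
remains defined near the boundary, falling back to Clopper–Pearson at x=0 or
x=n; the method actually used is recorded per interval, never silent.
Indeterminate results never enter any denominator — they are carried as a
separate count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import beta as _beta
from scipy.stats import norm as _norm

from .errors import DataError
from .panel import HLAAllele, Panel, parse_hla_allele

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "DiagnosticMetrics",
    "ConcordanceResult",
    "clopper_pearson_ci",
    "logit_ci",
    "diagnostic_metrics",
    "build_confusion",
    "concordance",
    "validation_report",
    "percent",
]


def percent(p: float, digits: int = 1) -> str:
    """Render a proportion as a half-up-rounded percentage string, e.g. 0.9924 -> '99.24%'."""
    q = Decimal(1).scaleb(-digits)
    return f"{Decimal(repr(float(p) * 100)).quantize(q, rounding=ROUND_HALF_UP)}%"


def round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of marker call vs reference carrier status.

    ``n_indeterminate`` counts samples whose composite marker result was
    indeterminate; they are excluded from the 2x2 cells.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_indeterminate: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "n_indeterminate"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise DataError(f"confusion count {name} must be a non-negative int, got {v!r}")

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


# ---------------------------------------------------------------------------
# confidence intervals

def clopper_pearson_ci(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval for x successes in n trials.

    lo = 0 at x=0 and hi = 1 at x=n by convention; at x=n the lower bound is
    the closed form (alpha/2)**(1/n).
    """
    if n < 1:
        raise ValueError("Clopper-Pearson interval undefined for n=0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    alpha = 1.0 - conf_level
    lo = 0.0 if x == 0 else float(_beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(_beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def logit_ci(
    x: float, n: float, conf_level: float = 0.95, adjusted: bool = False
) -> tuple[float, float]:
    """Normal interval on the (optionally adjusted) log-odds, back-transformed.

    Standard form requires 0 < x < n (raises ValueError at the boundary —
    callers should fall back to :func:`clopper_pearson_ci`).  The adjusted
    form adds 0.5 to each cell and is defined at the boundary.
    """
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    if adjusted:
        a, b = x + 0.5, n - x + 0.5
    else:
        if x <= 0 or x >= n:
            raise ValueError(
                "standard logit interval undefined at x=0 or x=n; "
                "use adjusted=True or Clopper-Pearson"
            )
        a, b = float(x), float(n - x)
    z = float(_norm.ppf(1 - (1 - conf_level) / 2))
    centre = math.log(a / b)
    se = math.sqrt(1 / a + 1 / b)
    expit = lambda t: 1.0 / (1.0 + math.exp(-t))
    return expit(centre - z * se), expit(centre + z * se)


_CI_METHODS = ("clopper_pearson", "standard_logit", "adjusted_logit")


def _proportion_ci(
    x: int, n: int, method: str, conf_level: float
) -> tuple[tuple[float, float], str]:
    """Interval plus the method actually used (boundary fallback is explicit)."""
    if method == "clopper_pearson":
        return clopper_pearson_ci(x, n, conf_level), method
    if method in ("standard_logit", "adjusted_logit"):
        adjusted = method == "adjusted_logit"
        if not adjusted and (x == 0 or x == n):
            return clopper_pearson_ci(x, n, conf_level), "clopper_pearson"
        if adjusted and (x == 0 or x == n):
            # degenerate estimate: exact interval is the defensible choice
            return clopper_pearson_ci(x, n, conf_level), "clopper_pearson"
        return logit_ci(x, n, conf_level, adjusted=adjusted), method
    raise ValueError(f"unknown CI method {method!r}; expected one of {_CI_METHODS}")


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its CI; ``value`` is None when the denominator is 0."""

    value: float | None
    lo: float | None = None
    hi: float | None = None
    ci_method: str = ""
    x: int = 0
    n: int = 0

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    conf_level: float = 0.95

    def as_dict(self) -> dict:
        out: dict = {"conf_level": self.conf_level}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: MetricEstimate = getattr(self, name)
            out[name] = None if not m.defined else {
                "value": m.value, "lo": m.lo, "hi": m.hi,
                "ci_method": m.ci_method, "x": m.x, "n": m.n,
            }
        return out


def diagnostic_metrics(
    t: ConfusionTable,
    rate_ci_method: str = "clopper_pearson",
    predictive_ci_method: str = "adjusted_logit",
    conf_level: float = 0.95,
) -> DiagnosticMetrics:
    """Point estimates and CIs for sensitivity, specificity, PPV and NPV.

    Degenerate denominators yield undefined metrics (never 0/0 -> 0).
    """
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")

    def est(x: int, n: int, method: str) -> MetricEstimate:
        if n == 0:
            return MetricEstimate(None, x=x, n=n)
        (lo, hi), used = _proportion_ci(x, n, method, conf_level)
        return MetricEstimate(x / n, lo, hi, used, x, n)

    return DiagnosticMetrics(
        sensitivity=est(t.tp, t.tp + t.fn, rate_ci_method),
        specificity=est(t.tn, t.tn + t.fp, rate_ci_method),
        ppv=est(t.tp, t.tp + t.fp, predictive_ci_method),
        npv=est(t.tn, t.tn + t.fn, predictive_ci_method),
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# confusion building

def build_confusion(
    inferences: Iterable,
    references: Iterable,
    target: HLAAllele | str,
    resolution: int = 2,
) -> ConfusionTable:
    """Partition carrier inferences against reference typings into a 2x2 table.

    ``inferences`` are objects with ``sample_id`` and ``status`` in
    {positive, negative, indeterminate} (e.g. CarrierInference);
    ``references`` are :class:`~hlatag.genotype_io.ReferenceTyping` records.
    A reference carrier is a sample whose typing matches ``target`` on
    either allele at the working resolution.  Indeterminate inferences are
    counted separately and excluded from the cells.
    """
    target = parse_hla_allele(target) if isinstance(target, str) else target
    ref_by_sample: dict[str, object] = {}
    for r in references:
        if r.locus == target.locus:
            ref_by_sample[r.sample_id] = r
    tp = fp = fn = tn = n_ind = 0
    missing: list[str] = []
    for inf in inferences:
        if inf.status == "indeterminate":
            n_ind += 1
            continue
        ref = ref_by_sample.get(inf.sample_id)
        if ref is None:
            missing.append(inf.sample_id)
            continue
        truth = ref.carries(target, resolution)
        if inf.status == "positive":
            tp += truth
            fp += not truth
        elif inf.status == "negative":
            fn += truth
            tn += not truth
        else:  # pragma: no cover - guarded by CarrierInference
            raise DataError(f"unknown inference status {inf.status!r}")
    if missing:
        raise DataError(
            f"samples lack a reference typing at locus {target.locus}: {sorted(set(missing))}"
        )
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn, n_indeterminate=n_ind)


# ---------------------------------------------------------------------------
# concordance

@dataclass(frozen=True)
class ConcordanceResult:
    proportion: float
    n_evaluable: int
    n_excluded: int
    discordant: tuple[str, ...]

    def __str__(self) -> str:
        return (
            f"concordance {percent(self.proportion, 2)} "
            f"({self.n_evaluable - len(self.discordant)}/{self.n_evaluable} pairs, "
            f"{self.n_excluded} excluded)"
        )


def concordance(calls_a: Mapping, calls_b: Mapping) -> ConcordanceResult:
    """Agreement proportion between two per-sample call mappings.

    Inputs map sample_id to any comparable determinate value; ``None`` (or
    the string ``"indeterminate"``) marks an indeterminate result and the
    pair is excluded and counted.  Raises on disjoint sample sets.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise DataError("concordance: the two call sets share no samples")

    def _det(v):
        return v is not None and v != "indeterminate"

    evaluable = [s for s in shared if _det(calls_a[s]) and _det(calls_b[s])]
    n_excl = len(shared) - len(evaluable)
    if not evaluable:
        raise DataError("concordance: no pair is determinate on both sides")
    discordant = tuple(s for s in evaluable if calls_a[s] != calls_b[s])
    prop = (len(evaluable) - len(discordant)) / len(evaluable)
    return ConcordanceResult(prop, len(evaluable), n_excl, discordant)


# ---------------------------------------------------------------------------
# report rendering

def _metric_lines(m: DiagnosticMetrics) -> list[tuple[str, str, str]]:
    rows = []
    for label, est in (
        ("Sensitivity", m.sensitivity),
        ("Specificity", m.specificity),
        ("Positive predictive value", m.ppv),
        ("Negative predictive value", m.npv),
    ):
        if not est.defined:
            rows.append((label, "undefined", "-"))
        else:
            ci = f"{percent(est.lo)} to {percent(est.hi)} [{est.ci_method}]"
            rows.append((label, percent(est.value), ci))
    return rows


def validation_report(
    panel: Panel,
    inferences: Sequence,
    references: Sequence,
    rate_ci_method: str = "clopper_pearson",
    predictive_ci_method: str = "adjusted_logit",
    conf_level: float = 0.95,
) -> dict:
    """Build the full validation report: one 2x2 block per evaluation unit.

    ``inferences`` must carry a ``unit`` label (which marker or rule produced
    them) and a ``target``; they are grouped by (unit, target).  Returns a
    dict with a machine-readable ``units`` list and a byte-stable markdown
    rendering under ``"markdown"``.
    """
    groups: dict[tuple[str, str], list] = {}
    for inf in inferences:
        groups.setdefault((inf.unit, inf.target.two_field), []).append(inf)

    units = []
    md: list[str] = ["# Carrier-inference validation report", ""]
    if not groups:
        md.append("(no evaluable inferences)")
    for (unit, target), infs in sorted(groups.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        table = build_confusion(infs, references, target)
        metrics = diagnostic_metrics(
            table, rate_ci_method, predictive_ci_method, conf_level
        )
        units.append(
            {
                "unit": unit,
                "target": target,
                "counts": {
                    "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
                    "n_indeterminate": table.n_indeterminate,
                    "n_evaluable": table.n_evaluable,
                },
                "metrics": metrics.as_dict(),
            }
        )
        md += [
            f"## {target} vs {unit}",
            "",
            f"|  | {unit}-Positive | {unit}-Negative |",
            "| --- | --- | --- |",
            f"| Real positive {target} | {table.tp} | {table.fn} |",
            f"| Real negative {target} | {table.fp} | {table.tn} |",
            "",
            f"| Metric | Value | {percent(conf_level, 0)} CI |",
            "| --- | --- | --- |",
        ]
        md += [f"| {l} | {v} | {ci} |" for l, v, ci in _metric_lines(metrics)]
        if table.n_indeterminate:
            md.append(f"\nIndeterminate (excluded): {table.n_indeterminate}")
        md.append("")
    doc = {
        "schema": "hlatag/validation-report/1",
        "conf_level": conf_level,
        "units": units,
    }
    doc["markdown"] = "\n".join(md)
    doc["json"] = json.dumps({k: v for k, v in doc.items() if k != "markdown"},
                             indent=2, sort_keys=True)
    return doc
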