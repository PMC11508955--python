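"""Model/Results interface for panel validation.

:class:`CarrierValidation` is built from per-sample genotype calls, a
reference HLA typing table and an assay panel; :meth:`CarrierValidation.fit`
evaluates every *evaluation unit* of the panel — each combination rule, each
standalone marker group of a multi-group rule, and each non-clinical assay —
against the reference typings and returns a
:class:`CarrierValidationResults` carrying confusion tables, the four
diagnostic metrics with confidence intervals, zygosity-concordance counts
and inter-marker discrepancy lists, with a ``summary()`` in the familiar
one-block-per-table layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import inference as inf_mod
from .errors import DataError
from .genotype_io import (
    GenotypeCall,
    ReferenceTyping,
    read_calls_table,
    read_calls_vcf,
    read_reference_typings,
)
from .inference import CarrierInference, MarkerStatus, infer_carrier, marker_status
from .panel import Panel, PanelRule, default_panel, parse_hla_allele
from .stats import (
    ConfusionTable,
    DiagnosticMetrics,
    build_confusion,
    diagnostic_metrics,
    percent,
    validation_report,
)

__all__ = ["CarrierValidation", "CarrierValidationResults", "EvaluationUnit", "UnitResult"]


@dataclass(frozen=True)
class EvaluationUnit:
    """One marker-or-rule to be compared against the reference typings."""

    label: str
    rule: PanelRule
    clinical: bool = True
    kind: str = "rule"  # rule | group | assay


@dataclass(frozen=True)
class UnitResult:
    unit: EvaluationUnit
    inferences: tuple[CarrierInference, ...]
    confusion: ConfusionTable
    metrics: DiagnosticMetrics
    n_skipped: int = 0  # samples lacking a call for some member assay


def _group_label(panel: Panel, group: Sequence[str]) -> str:
    rsids = {panel.assays[a].rsid for a in group}
    if len(rsids) == 1 and next(iter(rsids)):
        return next(iter(rsids))
    return "|".join(group)


def _rule_label(panel: Panel, rule: PanelRule) -> str:
    glabels = [_group_label(panel, g) for g in rule.members]
    if rule.combinator == "SINGLE":
        return glabels[0]
    joiner = "+" if rule.combinator == "ALL" else "|"
    return joiner.join(glabels)


def enumerate_units(panel: Panel, include_nonclinical: bool = True) -> list[EvaluationUnit]:
    """All evaluation units of a panel, rules first, in stable order."""
    units: list[EvaluationUnit] = []
    for rule in panel.rules:
        units.append(EvaluationUnit(_rule_label(panel, rule), rule, kind="rule"))
        if len(rule.members) > 1:
            for group in rule.members:
                sub = PanelRule(
                    target=rule.target,
                    members=(tuple(group),) if len(group) == 1 else tuple((a,) for a in group),
                    combinator="SINGLE" if len(group) == 1 else "ANY",
                )
                units.append(
                    EvaluationUnit(_group_label(panel, group), sub, kind="group")
                )
    if include_nonclinical:
        for assay in panel.nonclinical_assays():
            if not assay.associated_target:
                continue
            sub = PanelRule(
                target=parse_hla_allele(assay.associated_target),
                members=((assay.assay_id,),),
                combinator="SINGLE",
            )
            units.append(
                EvaluationUnit(
                    assay.rsid or assay.assay_id, sub, clinical=False, kind="assay"
                )
            )
    return units


class CarrierValidation:
    """Diagnostic-accuracy model of an HLA surrogate-marker panel.

    Parameters
    ----------
    calls : iterable of GenotypeCall
        Per sample x assay determinate/indeterminate calls.
    references : iterable of ReferenceTyping
        Ground-truth HLA typings (the comparator).
    panel : Panel, optional
        Assay panel; the shipped default panel when omitted.
    """

    def __init__(
        self,
        calls: Iterable[GenotypeCall],
        references: Iterable[ReferenceTyping],
        panel: Panel | None = None,
    ) -> None:
        self.panel = panel if panel is not None else default_panel()
        self.calls = tuple(calls)
        self.references = tuple(references)
        unknown = sorted(
            {c.assay_id for c in self.calls} - set(self.panel.assays)
        )
        if unknown:
            raise DataError(f"calls reference assays absent from the panel: {unknown}")
        self._by_sample: dict[str, dict[str, GenotypeCall]] = {}
        for c in self.calls:
            slot = self._by_sample.setdefault(c.sample_id, {})
            if c.assay_id in slot:
                raise DataError(
                    f"duplicate call for ({c.sample_id}, {c.assay_id})"
                )
            slot[c.assay_id] = c

    @classmethod
    def from_files(
        cls,
        calls_path,
        reference_path,
        panel: Panel | None = None,
        calls_format: str = "table",
    ) -> "CarrierValidation":
        """Build the model from a calls table (or VCF) and a reference table."""
        panel = panel if panel is not None else default_panel()
        if calls_format == "vcf":
            calls, _ = read_calls_vcf(calls_path, panel)
        elif calls_format == "table":
            calls = read_calls_table(calls_path)
        else:
            raise ValueError(f"calls_format must be 'table' or 'vcf', got {calls_format!r}")
        refs = read_reference_typings(reference_path)
        return cls(calls, refs, panel)

    # -- inference ---------------------------------------------------------

    def marker_statuses(self, sample_id: str) -> dict[str, MarkerStatus]:
        """Interpreted marker statuses for every assay called on a sample."""
        out = {}
        for aid, call in self._by_sample.get(sample_id, {}).items():
            out[aid] = marker_status(call, self.panel.assays[aid])
        return out

    def infer(self, unit: EvaluationUnit) -> tuple[list[CarrierInference], int]:
        """Carrier inferences for one unit over all samples with complete calls."""
        needed = set(unit.rule.assay_ids)
        inferences = []
        skipped = 0
        for sid in sorted(self._by_sample):
            have = self._by_sample[sid]
            if not needed <= set(have):
                skipped += 1
                continue
            statuses = {
                aid: marker_status(have[aid], self.panel.assays[aid]) for aid in needed
            }
            inferences.append(infer_carrier(sid, statuses, unit.rule, unit=unit.label))
        return inferences, skipped

    def fit(
        self,
        rate_ci_method: str = "clopper_pearson",
        predictive_ci_method: str = "adjusted_logit",
        conf_level: float = 0.95,
        include_nonclinical: bool = True,
    ) -> "CarrierValidationResults":
        """Evaluate every unit and return the results object."""
        units = enumerate_units(self.panel, include_nonclinical)
        results: list[UnitResult] = []
        for unit in units:
            inferences, skipped = self.infer(unit)
            if not inferences:
                continue
            table = build_confusion(inferences, self.references, unit.rule.target)
            metrics = diagnostic_metrics(
                table, rate_ci_method, predictive_ci_method, conf_level
            )
            results.append(
                UnitResult(unit, tuple(inferences), table, metrics, skipped)
            )
        return CarrierValidationResults(self, tuple(results), conf_level)


class CarrierValidationResults:
    """Fitted validation results: one 2x2 block per evaluation unit."""

    def __init__(
        self,
        model: CarrierValidation,
        unit_results: tuple[UnitResult, ...],
        conf_level: float,
    ) -> None:
        self.model = model
        self.unit_results = unit_results
        self.conf_level = conf_level

    def __getitem__(self, label: str) -> UnitResult:
        for r in self.unit_results:
            if r.unit.label == label:
                return r
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [r.unit.label for r in self.unit_results]

    # -- derived reports ---------------------------------------------------

    def zygosity_report(self, target) -> inf_mod.ZygosityReport:
        """Marker zygosity vs reference allele copies for a target's rule unit."""
        target = parse_hla_allele(target) if isinstance(target, str) else target
        for r in self.unit_results:
            if r.unit.kind == "rule" and r.unit.rule.target.two_field == target.two_field:
                return inf_mod.zygosity_concordance(
                    r.inferences, self.model.references, target
                )
        raise KeyError(f"no fitted rule unit for target {target.two_field}")

    def discrepancies(self, target) -> pd.DataFrame:
        """Samples on which two evaluation units for one target disagree determinately."""
        target = parse_hla_allele(target) if isinstance(target, str) else target
        units = [
            r for r in self.unit_results
            if r.unit.rule.target.two_field == target.two_field and r.unit.kind != "rule"
        ]
        rows = []
        for i, a in enumerate(units):
            amap = {x.sample_id: x.status for x in a.inferences}
            for b in units[i + 1:]:
                bmap = {x.sample_id: x.status for x in b.inferences}
                for sid in sorted(set(amap) & set(bmap)):
                    sa, sb = amap[sid], bmap[sid]
                    if "indeterminate" in (sa, sb) or sa == sb:
                        continue
                    rows.append((sid, a.unit.label, sa, b.unit.label, sb))
        return pd.DataFrame(
            rows, columns=["sample_id", "unit_a", "status_a", "unit_b", "status_b"]
        )

    def report(self) -> dict:
        """Full machine-readable report (with a markdown rendering)."""
        all_inferences = [x for r in self.unit_results for x in r.inferences]
        return validation_report(
            self.model.panel, all_inferences, self.model.references,
            conf_level=self.conf_level,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per unit with counts and point metrics (proportions)."""
        rows = []
        for r in self.unit_results:
            m = r.metrics
            rows.append(
                {
                    "unit": r.unit.label,
                    "target": r.unit.rule.target.two_field,
                    "kind": r.unit.kind,
                    "clinical": r.unit.clinical,
                    "tp": r.confusion.tp, "fp": r.confusion.fp,
                    "fn": r.confusion.fn, "tn": r.confusion.tn,
                    "n_indeterminate": r.confusion.n_indeterminate,
                    "sensitivity": m.sensitivity.value,
                    "specificity": m.specificity.value,
                    "ppv": m.ppv.value,
                    "npv": m.npv.value,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        doc = self.report()
        return json.dumps(
            {k: v for k, v in doc.items() if k not in ("markdown", "json")},
            indent=2, sort_keys=True, **kwargs,
        )

    def summary(self) -> str:
        """Human-readable validation summary, one block per evaluation unit."""
        lines = [
            "Carrier-inference panel validation",
            "==================================",
            f"Samples with calls: {len(self.model._by_sample)}    "
            f"Reference typings: {len(self.model.references)}    "
            f"Confidence level: {percent(self.conf_level, 0)}",
            "",
        ]
        for r in self.unit_results:
            t, m = r.confusion, r.metrics
            tag = "" if r.unit.clinical else "  [non-clinical]"
            lines.append(f"{r.unit.rule.target.two_field} vs {r.unit.label} "
                         f"({r.unit.rule.combinator}){tag}")
            lines.append(f"  TP {t.tp}  FP {t.fp}  FN {t.fn}  TN {t.tn}"
                         + (f"  indeterminate {t.n_indeterminate}" if t.n_indeterminate else "")
                         + (f"  skipped {r.n_skipped}" if r.n_skipped else ""))
            for name, est in (
                ("Sensitivity", m.sensitivity), ("Specificity", m.specificity),
                ("PPV", m.ppv), ("NPV", m.npv),
            ):
                if est.defined:
                    lines.append(
                        f"  {name:<12} {percent(est.value):>7}  "
                        f"({percent(est.lo)} to {percent(est.hi)}, {est.ci_method})"
                    )
                else:
                    lines.append(f"  {name:<12} undefined (empty denominator)")
            lines.append("")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CarrierValidationResults: {len(self.unit_results)} units, "
            f"{len(self.model.references)} reference samples>"
        )
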