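"""Carrier inference: apply panel combination rules to per-sample marker calls.

The logic is deliberately Boolean, mirroring clinical screening practice:

* a ``snv_tag`` marker is positive when the sample carries at least one copy
  of the assay's configured tag allele (heterozygous or homozygous);
* an ``allele_specific`` marker is positive when the target channel was
  called positive;
* rules combine marker groups with SINGLE / ANY / ALL semantics, with
  three-valued handling of indeterminates: an ANY rule short-circuits on a
  positive member and an ALL rule on a determinate-negative member, so a
  result is indeterminate only when it genuinely cannot be decided.

Marker zygosity is additionally compared with the number of target-allele
copies in the reference typing: tag SNVs identify carriers well but do not
reliably count alleles, so any copy-number prediction is flagged
non-clinical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DataError
from .genotype_io import GenotypeCall, ReferenceTyping
from .panel import HLAAllele, PanelRule, SNVAssay

__all__ = [
    "MarkerStatus",
    "CarrierInference",
    "ZygosityReport",
    "marker_status",
    "infer_carrier",
    "predict_copies",
    "zygosity_concordance",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"

_AS_TOKENS = {POSITIVE, NEGATIVE}


@dataclass(frozen=True)
class MarkerStatus:
    """Interpreted state of one marker assay for one sample.

    ``zygosity`` is ``het``/``hom`` for positive tag-SNV markers, ``none``
    for negatives, and ``unknown`` for allele-specific positives (those
    assays carry no dose information) and indeterminates.
    """

    assay_id: str
    status: str
    zygosity: str = "unknown"

    def __post_init__(self) -> None:
        if self.status not in (POSITIVE, NEGATIVE, INDETERMINATE):
            raise DataError(f"invalid marker status {self.status!r}")
        if self.zygosity not in ("het", "hom", "none", "unknown"):
            raise DataError(f"invalid zygosity {self.zygosity!r}")
        if self.status == NEGATIVE and self.zygosity != "none":
            raise DataError("negative marker must have zygosity 'none'")
        if self.status == POSITIVE and self.zygosity == "none":
            raise DataError("positive marker cannot have zygosity 'none'")


def marker_status(call: GenotypeCall, assay: SNVAssay) -> MarkerStatus:
    """Interpret a raw genotype call as marker positivity for its assay."""
    if call.assay_id != assay.assay_id:
        raise DataError(
            f"call assay {call.assay_id!r} does not match assay {assay.assay_id!r}"
        )
    if not call.is_determinate:
        return MarkerStatus(assay.assay_id, INDETERMINATE, "unknown")

    if assay.mode == "allele_specific":
        token = call.alleles[0].lower() if len(call.alleles) == 1 else None
        if token not in _AS_TOKENS:
            raise DataError(
                f"{call.sample_id}/{assay.assay_id}: allele-specific call must be "
                f"'positive' or 'negative', got {call.alleles!r}"
            )
        if token == POSITIVE:
            return MarkerStatus(assay.assay_id, POSITIVE, "unknown")
        return MarkerStatus(assay.assay_id, NEGATIVE, "none")

    if len(call.alleles) != 2:
        raise DataError(
            f"{call.sample_id}/{assay.assay_id}: snv_tag call needs two alleles"
        )
    expected = assay.expected_alleles
    if expected and not any(a in expected for a in call.alleles):
        raise DataError(
            f"{call.sample_id}/{assay.assay_id}: alleles {call.alleles} are foreign "
            f"to assay alleles {sorted(expected)}"
        )
    n_tag = sum(a == assay.tag_allele for a in call.alleles)
    if n_tag == 0:
        return MarkerStatus(assay.assay_id, NEGATIVE, "none")
    return MarkerStatus(assay.assay_id, POSITIVE, "hom" if n_tag == 2 else "het")


@dataclass(frozen=True)
class CarrierInference:
    """Per sample x target carrier verdict with marker provenance.

    ``predicted_copies`` (1 or 2, from marker zygosity) is set only when all
    used markers are determinate and is always non-clinical: surrogate
    markers identify carriage, not allele dose.
    """

    sample_id: str
    target: HLAAllele
    status: str
    markers_used: tuple[MarkerStatus, ...]
    rule: PanelRule | None = None
    unit: str = ""
    predicted_copies: int | None = None
    non_clinical_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in (POSITIVE, NEGATIVE, INDETERMINATE):
            raise DataError(f"invalid inference status {self.status!r}")
        if self.predicted_copies is not None and "copy_number_non_clinical" not in self.non_clinical_flags:
            object.__setattr__(
                self,
                "non_clinical_flags",
                self.non_clinical_flags + ("copy_number_non_clinical",),
            )


def _combine_group(statuses: Sequence[str]) -> str:
    """ANY-combination within one assay group."""
    if POSITIVE in statuses:
        return POSITIVE
    if all(s == NEGATIVE for s in statuses):
        return NEGATIVE
    return INDETERMINATE


def _combine(group_statuses: Sequence[str], combinator: str) -> str:
    if combinator == "SINGLE":
        return group_statuses[0]
    if combinator == "ANY":
        return _combine_group(group_statuses)
    # ALL: one determinate negative falsifies the conjunction even when other
    # members are indeterminate — maximises determinate output.
    if NEGATIVE in group_statuses:
        return NEGATIVE
    if all(s == POSITIVE for s in group_statuses):
        return POSITIVE
    return INDETERMINATE


def infer_carrier(
    sample_id: str,
    markers: Mapping[str, MarkerStatus] | Sequence[MarkerStatus],
    rule: PanelRule,
    unit: str = "",
) -> CarrierInference:
    """Combine the rule's marker statuses into one carrier verdict (pure function)."""
    if not isinstance(markers, Mapping):
        markers = {m.assay_id: m for m in markers}
    used: list[MarkerStatus] = []
    group_statuses: list[str] = []
    for group in rule.members:
        statuses = []
        for aid in group:
            m = markers.get(aid)
            if m is None:
                raise DataError(
                    f"sample {sample_id}: no status for assay {aid} required by "
                    f"rule {rule.target.two_field}"
                )
            used.append(m)
            statuses.append(m.status)
        group_statuses.append(_combine_group(statuses))
    status = _combine(group_statuses, rule.combinator)
    copies = predict_copies(used) if status == POSITIVE else None
    return CarrierInference(
        sample_id=sample_id,
        target=rule.target,
        status=status,
        markers_used=tuple(used),
        rule=rule,
        unit=unit or "+".join(rule.assay_ids),
        predicted_copies=copies,
    )


def predict_copies(markers: Iterable[MarkerStatus]) -> int | None:
    """Naive allele-dose guess from marker zygosity (non-clinical).

    2 when every used marker with dose information is homozygous, 1 when any
    is heterozygous; None when any marker is indeterminate or no dose
    information exists.
    """
    zygs = [m.zygosity for m in markers]
    if any(m.status == INDETERMINATE for m in markers):
        return None
    informative = [z for z in zygs if z in ("het", "hom")]
    if not informative:
        return None
    return 2 if all(z == "hom" for z in informative) else 1


@dataclass(frozen=True)
class ZygosityReport:
    """Cross-tabulation of marker zygosity vs reference allele copies among
    true-positive carriers: rows het/hom marker, columns 1/2 copies."""

    het_1: int = 0
    hom_1: int = 0
    het_2: int = 0
    hom_2: int = 0
    n_uninformative: int = 0

    @property
    def total(self) -> int:
        return self.het_1 + self.hom_1 + self.het_2 + self.hom_2

    @property
    def n_discordant(self) -> int:
        return self.hom_1 + self.het_2

    def as_dict(self) -> dict:
        return {
            "het_marker_1_copy": self.het_1,
            "hom_marker_1_copy": self.hom_1,
            "het_marker_2_copies": self.het_2,
            "hom_marker_2_copies": self.hom_2,
            "uninformative": self.n_uninformative,
        }


def zygosity_concordance(
    inferences: Iterable[CarrierInference],
    references: Iterable[ReferenceTyping],
    target: HLAAllele,
    resolution: int = 2,
) -> ZygosityReport:
    """Compare marker zygosity with reference allele count for true carriers.

    Only determinate-positive inferences whose sample is a reference carrier
    enter the table (its total equals the number of true positives); samples
    whose markers carry no dose information (allele-specific assays) are
    counted as uninformative.
    """
    refs = {r.sample_id: r for r in references if r.locus == target.locus}
    het_1 = hom_1 = het_2 = hom_2 = uninf = 0
    for inf in inferences:
        if inf.status != POSITIVE:
            continue
        ref = refs.get(inf.sample_id)
        if ref is None or not ref.carries(target, resolution):
            continue
        copies = min(ref.copies(target, resolution), 2)
        zygs = [m.zygosity for m in inf.markers_used if m.zygosity in ("het", "hom")]
        if not zygs:
            uninf += 1
            continue
        hom = all(z == "hom" for z in zygs)
        if copies >= 2:
            hom_2 += hom
            het_2 += not hom
        else:
            hom_1 += hom
            het_1 += not hom
    return ZygosityReport(het_1, hom_1, het_2, hom_2, uninf)
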