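"""Assay-panel data model: HLA nomenclature, assays, combination rules, config I/O.

A screening panel maps each pharmacogenomically relevant HLA allele (the
*target*) to one or more TaqMan assays and a Boolean combination rule.  Two
assay modes exist:

* ``snv_tag`` — a genotyping assay for a surrogate SNV in linkage
  disequilibrium with the target; a sample is marker-positive when it carries
  at least one copy of the configured tag allele.
* ``allele_specific`` — an allele-specific amplification read out against an
  internal reference channel (e.g. ß-Globin) and called positive/negative
  from the allelic-discrimination plot.

Rules combine *groups* of assays.  A group is positive when any of its
member assays is positive (this is how a single SNV covered by two assay
designs is handled); the rule's combinator (SINGLE / ANY / ALL) then applies
across groups.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import AlleleParseError, PanelError

__all__ = [
    "HLAAllele",
    "SNVAssay",
    "PanelRule",
    "Panel",
    "parse_hla_allele",
    "allele_match",
    "load_panel",
    "save_panel",
    "default_panel",
]

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z]+[0-9]*)\*(?P<fields>\d+(?::\d+)*)(?P<suffix>[NLSCAQ]?)$"
)

#: Expression suffixes marking alleles with aberrant expression; ``N`` is null.
EXPRESSION_SUFFIXES = frozenset("NLSCAQ")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A parsed HLA allele name, e.g. ``B*57:01`` (two-field resolution minimum).

    Attributes
    ----------
    locus : str
        Gene locus, e.g. ``"A"`` or ``"B"``.
    fields : tuple of int
        Colon-separated numeric fields; at least two (allele group, protein).
    raw : str
        The original string, preserving resolution and expression suffix.
    suffix : str
        Expression-variant suffix (``N``, ``L``, ``Q`` ...) or empty.
    """

    locus: str
    fields: tuple[int, ...]
    raw: str = field(compare=False, default="")
    suffix: str = ""

    def __post_init__(self) -> None:
        if not self.locus:
            raise AlleleParseError("HLA allele locus must be non-empty")
        if len(self.fields) < 2:
            raise AlleleParseError(
                f"HLA allele {self.raw or self.locus!r} needs at least two fields"
            )
        if not self.raw:
            object.__setattr__(self, "raw", self.two_field + self.suffix)

    @property
    def two_field(self) -> str:
        """Canonical two-field form, e.g. ``"B*58:01"``."""
        return f"{self.locus}*{self.fields[0]:02d}:{self.fields[1]:02d}"

    @property
    def is_null(self) -> bool:
        return self.suffix == "N"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.two_field


def parse_hla_allele(text: str) -> HLAAllele:
    """Parse a WHO-nomenclature allele string into an :class:`HLAAllele`.

    Accepts ``LOCUS*FF:FF[:FF...]`` with an optional expression suffix;
    higher-resolution names are preserved in ``raw`` but compared at the
    requested resolution by :func:`allele_match`.

    >>> parse_hla_allele("B*58:01:01").two_field
    'B*58:01'
    """
    if not isinstance(text, str):
        raise AlleleParseError(f"expected string, got {type(text).__name__}")
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        # name the offending token for the error message
        tok = text.strip().split()[0] if text.strip() else "<empty>"
        raise AlleleParseError(f"malformed HLA allele string: {tok!r}")
    fields = tuple(int(f) for f in m.group("fields").split(":"))
    if len(fields) < 2:
        raise AlleleParseError(
            f"allele {text!r} has only {len(fields)} field(s); two-field resolution required"
        )
    return HLAAllele(
        locus=m.group("locus"),
        fields=fields,
        raw=text.strip(),
        suffix=m.group("suffix"),
    )


def allele_match(
    a: HLAAllele | str,
    b: HLAAllele | str,
    resolution: int = 2,
    null_mismatches: bool = True,
) -> bool:
    """True iff two alleles agree on locus and the first ``resolution`` fields.

    Reference typings are often higher resolution than the two-field panel
    targets; extra fields are ignored.  With ``null_mismatches`` (default), an
    expression-suffixed null allele (``N``) never matches a non-null name:
    a non-expressed allele is conservatively treated as not carried.
    """
    if isinstance(a, str):
        a = parse_hla_allele(a)
    if isinstance(b, str):
        b = parse_hla_allele(b)
    if null_mismatches and (a.is_null != b.is_null):
        return False
    return (
        a.locus == b.locus
        and a.fields[:resolution] == b.fields[:resolution]
        and len(a.fields) >= resolution
        and len(b.fields) >= resolution
    )


_MODES = ("snv_tag", "allele_specific")
_COMBINATORS = ("SINGLE", "ANY", "ALL")


@dataclass(frozen=True)
class SNVAssay:
    """One TaqMan assay of the panel.

    ``tag_allele``/``other_allele`` give the orientation of a ``snv_tag``
    assay: carrying >=1 tag allele makes the marker positive.  These are
    configuration data, not inferred.  ``associated_target`` records which
    HLA allele the assay surrogates (panel-table column), including for
    assays excluded from clinical rules (``clinical=False``).
    """

    assay_id: str
    mode: str = "snv_tag"
    rsid: str = ""
    tag_allele: str = ""
    other_allele: str = ""
    reference_channel: str = ""
    associated_target: str = ""
    clinical: bool = True
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise PanelError(f"assay {self.assay_id}: unknown mode {self.mode!r}")
        if self.mode == "snv_tag" and (not self.rsid or not self.tag_allele):
            raise PanelError(
                f"assay {self.assay_id}: snv_tag mode requires rsid and tag_allele"
            )
        if self.mode == "allele_specific" and not self.reference_channel:
            raise PanelError(
                f"assay {self.assay_id}: allele_specific mode requires reference_channel"
            )

    @property
    def expected_alleles(self) -> frozenset[str]:
        """Nucleotides a determinate call at this assay may contain (if known)."""
        return frozenset(a for a in (self.tag_allele, self.other_allele) if a)


@dataclass(frozen=True)
class PanelRule:
    """Combination rule producing one carrier verdict per sample.

    ``members`` is a list of groups, each a list of assay ids.  Within a
    group assays are ANY-combined; the combinator applies across groups.
    """

    target: HLAAllele
    members: tuple[tuple[str, ...], ...]
    combinator: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.combinator not in _COMBINATORS:
            raise PanelError(f"invalid combinator {self.combinator!r}")
        groups = [tuple(g) for g in self.members]
        object.__setattr__(self, "members", tuple(groups))
        n_groups = len(groups)
        if any(len(g) == 0 for g in groups):
            raise PanelError(f"rule for {self.target}: empty assay group")
        if self.combinator == "SINGLE":
            if n_groups != 1 or len(groups[0]) != 1:
                raise PanelError(
                    f"rule for {self.target}: SINGLE requires exactly one group of one assay"
                )
        elif n_groups < 2:
            raise PanelError(
                f"rule for {self.target}: {self.combinator} requires >=2 groups"
            )

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(a for g in self.members for a in g)


@dataclass(frozen=True)
class Panel:
    """A validated assay panel: assays keyed by id plus combination rules."""

    assays: Mapping[str, SNVAssay]
    rules: tuple[PanelRule, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "assays", dict(self.assays))
        object.__setattr__(self, "rules", tuple(self.rules))
        for aid, assay in self.assays.items():
            if aid != assay.assay_id:
                raise PanelError(f"assay key {aid!r} != assay_id {assay.assay_id!r}")
        seen_targets: set[str] = set()
        for rule in self.rules:
            key = rule.target.two_field
            if key in seen_targets:
                raise PanelError(f"duplicate rule target {key}")
            seen_targets.add(key)
            for aid in rule.assay_ids:
                if aid not in self.assays:
                    raise PanelError(
                        f"rule for {key} references unknown assay {aid!r}"
                    )

    def rule_for(self, target: HLAAllele | str) -> PanelRule:
        t = parse_hla_allele(target) if isinstance(target, str) else target
        for rule in self.rules:
            if rule.target.two_field == t.two_field:
                return rule
        raise PanelError(f"no rule for target {t.two_field}")

    def assays_by_rsid(self, rsid: str) -> list[SNVAssay]:
        return [a for a in self.assays.values() if a.rsid == rsid]

    def nonclinical_assays(self) -> list[SNVAssay]:
        return [a for a in self.assays.values() if not a.clinical]


# ---------------------------------------------------------------------------
# config serialisation

def _assay_to_dict(a: SNVAssay) -> dict:
    d: dict = {"id": a.assay_id, "mode": a.mode}
    for key in ("rsid", "tag_allele", "other_allele", "reference_channel",
                "associated_target"):
        if getattr(a, key):
            d[key] = getattr(a, key)
    if not a.clinical:
        d["clinical"] = False
    if a.metadata:
        d["metadata"] = dict(a.metadata)
    return d


def panel_to_dict(panel: Panel) -> dict:
    """Serialise a panel to a plain config mapping (YAML/JSON compatible)."""
    return {
        "schema_version": panel.version,
        "assays": [_assay_to_dict(a) for a in panel.assays.values()],
        "rules": [
            {
                "target": r.target.two_field,
                "combinator": r.combinator,
                "members": [list(g) for g in r.members],
                **({"notes": r.notes} if r.notes else {}),
            }
            for r in panel.rules
        ],
    }


def save_panel(panel: Panel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(panel_to_dict(panel), sort_keys=False))


def load_panel(source) -> Panel:
    """Load and validate a panel from a mapping, YAML/JSON text, path or stream.

    Raises :class:`PanelError` on dangling assay references, duplicate ids or
    invalid combinators.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text()
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "assays" not in doc or "rules" not in doc:
        raise PanelError("panel config must contain 'assays' and 'rules'")

    assays: dict[str, SNVAssay] = {}
    for entry in doc["assays"]:
        aid = entry.get("id") or entry.get("assay_id")
        if not aid:
            raise PanelError(f"assay entry missing id: {entry!r}")
        if aid in assays:
            raise PanelError(f"duplicate assay id {aid!r}")
        assays[aid] = SNVAssay(
            assay_id=aid,
            mode=entry.get("mode", "snv_tag"),
            rsid=entry.get("rsid", ""),
            tag_allele=entry.get("tag_allele", ""),
            other_allele=entry.get("other_allele", ""),
            reference_channel=entry.get("reference_channel", ""),
            associated_target=entry.get("associated_target", ""),
            clinical=bool(entry.get("clinical", True)),
            metadata=entry.get("metadata", {}) or {},
        )
    rules = tuple(
        PanelRule(
            target=parse_hla_allele(r["target"]),
            members=tuple(tuple(g) for g in r["members"]),
            combinator=r["combinator"],
            notes=r.get("notes", ""),
        )
        for r in doc["rules"]
    )
    return Panel(assays=assays, rules=rules, version=str(doc.get("schema_version", "1")))


def default_panel() -> Panel:
    """The shipped default screening panel (11 assays, 4 targets)."""
    with resources.files("hlatag.data").joinpath("default_panel.yaml").open() as fh:
        return load_panel(fh)
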