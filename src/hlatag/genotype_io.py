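"""Readers and writers for genotype-call tables, minimal VCF, and reference typings.

The tabular call schema (``sample_id, assay_id, allele1, allele2, status``)
is this package's own exchange format — genotyping instruments export many
dialects, so a minimal explicit one is defined here.  VCF input is standard
VCF 4.x consumed at the GT level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import DataError
from .panel import HLAAllele, Panel, parse_hla_allele

__all__ = [
    "GenotypeCall",
    "ReferenceTyping",
    "read_calls_table",
    "write_calls_table",
    "read_calls_vcf",
    "read_reference_typings",
    "write_reference_typings",
]

DETERMINATE = "determinate"
INDETERMINATE = "indeterminate"

#: status column spellings accepted as indeterminate
_INDET_TOKENS = {"indeterminate", "undetermined", "no_call", "nc", "na", "?"}


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """One sample x assay call.

    For ``snv_tag`` assays a determinate call carries exactly two nucleotide
    alleles (unordered; stored lexicographically — carrier logic is
    zygosity-level, so phase is irrelevant).  For ``allele_specific`` assays
    it carries a single ``positive``/``negative`` token.  Indeterminate
    calls carry no alleles.
    """

    sample_id: str
    assay_id: str
    alleles: tuple[str, ...] = ()
    status: str = DETERMINATE

    def __post_init__(self) -> None:
        if self.status not in (DETERMINATE, INDETERMINATE):
            raise DataError(f"invalid call status {self.status!r}")
        alleles = tuple(self.alleles)
        if self.status == INDETERMINATE:
            if alleles:
                raise DataError(
                    f"indeterminate call {self.sample_id}/{self.assay_id} must carry no alleles"
                )
        else:
            if len(alleles) == 2:
                alleles = tuple(sorted(alleles))
            elif len(alleles) != 1:
                raise DataError(
                    f"determinate call {self.sample_id}/{self.assay_id} needs 1 "
                    f"(positive/negative) or 2 (diploid) alleles, got {len(alleles)}"
                )
        object.__setattr__(self, "alleles", alleles)

    @property
    def is_determinate(self) -> bool:
        return self.status == DETERMINATE


@dataclass(frozen=True)
class ReferenceTyping:
    """Reference (ground-truth) HLA typing of one sample at one locus."""

    sample_id: str
    locus: str
    alleles: tuple[HLAAllele, HLAAllele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        for al in (a, b):
            if al.locus != self.locus:
                raise DataError(
                    f"sample {self.sample_id}: allele {al.raw} is not at locus {self.locus}"
                )

    def carries(self, target: HLAAllele, resolution: int = 2) -> bool:
        from .panel import allele_match

        return any(allele_match(a, target, resolution) for a in self.alleles)

    def copies(self, target: HLAAllele, resolution: int = 2) -> int:
        from .panel import allele_match

        return sum(allele_match(a, target, resolution) for a in self.alleles)


# ---------------------------------------------------------------------------
# tabular calls

def _read_delimited(source, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else None  # None -> sniff , vs tab
    return pd.read_csv(
        source, sep=sep, engine="python", dtype=str, keep_default_na=False,
        encoding="utf-8", skipinitialspace=True,
    )


def read_calls_table(source, delimiter: str | None = None) -> list[GenotypeCall]:
    """Read genotype calls from delimited text (TSV/CSV, auto-detected).

    Required columns: ``sample_id``, ``assay_id``, ``allele1``, ``allele2``;
    optional ``status`` (defaults determinate; ``undetermined`` and friends
    map to indeterminate).  Allele-specific assay rows put the
    positive/negative token in ``allele1`` and leave ``allele2`` empty.
    Unknown assay ids are allowed here and validated at inference time.
    """
    df = _read_delimited(source, delimiter)
    required = {"sample_id", "assay_id", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"calls table missing column(s): {', '.join(sorted(missing))}")
    dup = df.duplicated(subset=["sample_id", "assay_id"], keep=False)
    if dup.any():
        keys = sorted(
            set(map(tuple, df.loc[dup, ["sample_id", "assay_id"]].itertuples(index=False)))
        )
        raise DataError(f"duplicate (sample_id, assay_id) rows: {keys}")
    calls: list[GenotypeCall] = []
    for row in df.itertuples(index=False):
        status = getattr(row, "status", DETERMINATE).strip().lower() or DETERMINATE
        if status in _INDET_TOKENS:
            calls.append(GenotypeCall(row.sample_id, row.assay_id, (), INDETERMINATE))
            continue
        if status != DETERMINATE:
            raise DataError(
                f"row ({row.sample_id}, {row.assay_id}): unknown status {status!r}"
            )
        alleles = tuple(a for a in (row.allele1.strip(), row.allele2.strip()) if a)
        calls.append(GenotypeCall(row.sample_id, row.assay_id, alleles))
    return calls


def write_calls_table(calls: Iterable[GenotypeCall], path, delimiter: str = "\t") -> None:
    rows = []
    for c in sorted(calls):
        a1 = c.alleles[0] if len(c.alleles) >= 1 else ""
        a2 = c.alleles[1] if len(c.alleles) >= 2 else ""
        rows.append((c.sample_id, c.assay_id, a1, a2, c.status))
    pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "allele1", "allele2", "status"]
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# VCF

def read_calls_vcf(path, panel: Panel) -> tuple[list[GenotypeCall], int]:
    """Extract panel-assay genotype calls from a VCF (GT field only).

    Records are matched to assays by the ID column (rsID); an rsID covered by
    more than one assay design (e.g. a SNV with two TaqMan designs) feeds a
    call to every matching assay.  ``./.`` genotypes become indeterminate
    calls; phasing is ignored; multi-allelic records are resolved through the
    GT allele index.

    Returns
    -------
    (calls, n_unmatched) : matched calls plus the count of VCF records whose
    ID is not a panel rsID (useful as a warning signal).
    """
    rsids = {a.rsid for a in panel.assays.values() if a.rsid}
    calls: list[GenotypeCall] = []
    n_unmatched = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rid = rec.id or ""
            if rid not in rsids:
                n_unmatched += 1
                continue
            assays = panel.assays_by_rsid(rid)
            site_alleles = rec.alleles  # (ref, alt1, ...)
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(i is None for i in gt):
                    for assay in assays:
                        calls.append(
                            GenotypeCall(sample, assay.assay_id, (), INDETERMINATE)
                        )
                    continue
                if len(gt) != 2:
                    raise DataError(
                        f"{rid}/{sample}: expected diploid GT, got ploidy {len(gt)}"
                    )
                pair = tuple(site_alleles[i] for i in gt)
                for assay in assays:
                    calls.append(GenotypeCall(sample, assay.assay_id, pair))
    return calls, n_unmatched


# ---------------------------------------------------------------------------
# reference typings

def read_reference_typings(source, delimiter: str | None = None) -> list[ReferenceTyping]:
    """Read a reference HLA typing table (``sample_id, locus, allele1, allele2``).

    Alleles are parsed as WHO nomenclature; a sample may have at most one
    record per locus, and both alleles must be at the stated locus.
    """
    df = _read_delimited(source, delimiter)
    required = {"sample_id", "locus", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(
            f"reference typing table missing column(s): {', '.join(sorted(missing))}"
        )
    dup = df.duplicated(subset=["sample_id", "locus"], keep=False)
    if dup.any():
        keys = sorted(set(map(tuple, df.loc[dup, ["sample_id", "locus"]].itertuples(index=False))))
        raise DataError(f"duplicate (sample_id, locus) reference rows: {keys}")
    out = []
    for row in df.itertuples(index=False):
        a1 = parse_hla_allele(row.allele1)
        a2 = parse_hla_allele(row.allele2)
        out.append(ReferenceTyping(row.sample_id, row.locus.strip(), (a1, a2)))
    return out


def write_reference_typings(
    typings: Iterable[ReferenceTyping], path, delimiter: str = "\t"
) -> None:
    rows = [
        (t.sample_id, t.locus, t.alleles[0].raw, t.alleles[1].raw)
        for t in sorted(typings, key=lambda t: (t.sample_id, t.locus))
    ]
    pd.DataFrame(rows, columns=["sample_id", "locus", "allele1", "allele2"]).to_csv(
        path, sep=delimiter, index=False
    )
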