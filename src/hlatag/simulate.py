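"""Synthetic cohorts and fluorescence data with the statistical structure the
validation pipeline assumes.

The generator is phenomenological: carrier copy numbers follow Hardy–Weinberg
proportions for a target allele frequency ``p``; each marker assay fires with
its own tagging sensitivity sigma (P(marker+ | carrier)) and specificity tau
(P(marker- | non-carrier)); marker zygosity mirrors copy number except at a
configurable discordance rate (tag SNVs identify carriers, not allele dose);
indeterminate wells are injected at a flat rate; endpoint fluorescence is an
isotropic Gaussian cloud around per-class centroids, clipped at zero, plus
no-template-control wells near the origin.  No haplotype/LD structure is
simulated — tagging error is captured entirely by (sigma, tau).

All draws flow through one seeded ``numpy`` generator, so equal seeds give
byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import AS_CLASSES, SNV_CLASSES, FluorescencePoint
from .errors import DataError
from .genotype_io import DETERMINATE, INDETERMINATE, GenotypeCall, ReferenceTyping
from .panel import HLAAllele, Panel, SNVAssay, default_panel, parse_hla_allele
from .stats import ConfusionTable

__all__ = [
    "MarkerSpec",
    "FluorescenceSpec",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_fluorescence",
    "fixture_from_confusion",
    "crossed_two_marker_fixture",
]

#: filler (non-target) alleles per locus for reference typings; chosen to
#: exercise near-miss two-field matching (e.g. B*58:06 vs B*58:01).
FILLER_ALLELES: dict[str, tuple[str, ...]] = {
    "A": ("A*02:01", "A*01:01", "A*03:01", "A*24:02"),
    "B": ("B*07:02", "B*44:02", "B*58:06", "B*08:01"),
}


@dataclass(frozen=True)
class MarkerSpec:
    """Tagging operating characteristics of one assay."""

    assay_id: str
    sensitivity: float = 1.0   # P(marker positive | carrier)
    specificity: float = 1.0   # P(marker negative | non-carrier)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"marker {self.assay_id}: {name} must be in [0,1]")


@dataclass(frozen=True)
class FluorescenceSpec:
    """Per-class fluorescence cloud parameters (arbitrary units).

    ``centroids`` maps class labels (``negative``/``positive`` or
    ``homo_allele1``/``het``/``homo_allele2``) to (fam, vic) means;
    ``sigma`` is the isotropic cloud SD; ``n_ntc`` no-template wells are
    emitted near ``ntc_level``.
    """

    centroids: Mapping[str, tuple[float, float]]
    sigma: float = 0.05
    n_ntc: int = 3
    ntc_level: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataError("fluorescence sigma must be >= 0")
        cents = {k: tuple(map(float, v)) for k, v in dict(self.centroids).items()}
        if len(set(cents.values())) != len(cents):
            raise DataError("fluorescence centroids must be distinct")
        object.__setattr__(self, "centroids", cents)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic validation cohort."""

    n_samples: int
    target: str = "B*57:01"
    markers: tuple[MarkerSpec, ...] = ()
    allele_frequency: float | None = None     # HWE p for the target allele
    carrier_prevalence: float | None = None   # pi = 1 - (1-p)^2 when p given
    correlation: str = "independent"          # or "comonotone"
    zygosity_discordance_rate: float = 0.0
    indeterminate_rate: float = 0.0
    fluorescence: FluorescenceSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise DataError("n_samples must be >= 1")
        if self.correlation not in ("independent", "comonotone"):
            raise DataError(f"unknown marker correlation {self.correlation!r}")
        for name in ("zygosity_discordance_rate", "indeterminate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0,1]")
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise DataError("at least one MarkerSpec is required")

    def resolved_allele_frequency(self) -> float:
        """HWE allele frequency implied by the config; errors on inconsistency."""
        p, pi = self.allele_frequency, self.carrier_prevalence
        if p is not None:
            if not 0.0 <= p <= 1.0:
                raise DataError("allele_frequency must be in [0,1]")
            if pi is not None:
                implied = 1.0 - (1.0 - p) ** 2
                if abs(implied - pi) > 1e-9:
                    raise DataError(
                        f"carrier_prevalence {pi} inconsistent with allele_frequency "
                        f"{p} (HWE implies {implied:.6f})"
                    )
            return p
        if pi is not None:
            if not 0.0 <= pi <= 1.0:
                raise DataError("carrier_prevalence must be in [0,1]")
            return 1.0 - math.sqrt(1.0 - pi)
        raise DataError("one of allele_frequency / carrier_prevalence is required")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generator output: ground truth plus the observable layers."""

    config: SimConfig
    references: tuple[ReferenceTyping, ...]
    samples: pd.DataFrame        # sample_id, carrier, copies
    marker_truth: pd.DataFrame   # sample_id, assay_id, true_positive, zygosity,
                                 # class_label, indeterminate
    calls: tuple[GenotypeCall, ...]


def _assay_lookup(config: SimConfig, panel: Panel | None) -> dict[str, SNVAssay]:
    pan = panel if panel is not None else default_panel()
    out = {}
    for spec in config.markers:
        assay = pan.assays.get(spec.assay_id)
        if assay is None:
            # ad-hoc assay outside any panel: generic tag SNV
            assay = SNVAssay(
                assay_id=spec.assay_id, rsid=spec.assay_id,
                tag_allele="T", other_allele="C",
            )
        out[spec.assay_id] = assay
    return out


def _reference_for(
    sample_id: str, target: HLAAllele, copies: int, rng: np.random.Generator
) -> ReferenceTyping:
    fillers = [
        f for f in FILLER_ALLELES.get(target.locus, ("X*99:99",))
        if parse_hla_allele(f).two_field != target.two_field
    ]
    pick = lambda: fillers[int(rng.integers(len(fillers)))]
    if copies >= 2:
        alleles = (target, target)
    elif copies == 1:
        alleles = (target, parse_hla_allele(pick()))
    else:
        alleles = (parse_hla_allele(pick()), parse_hla_allele(pick()))
    return ReferenceTyping(sample_id, target.locus, alleles)


def _call_for(
    sample_id: str, assay: SNVAssay, positive: bool, zygosity: str
) -> tuple[GenotypeCall, str]:
    """Build the observable call and the fluorescence class label."""
    if assay.mode == "allele_specific":
        token = "positive" if positive else "negative"
        return GenotypeCall(sample_id, assay.assay_id, (token,)), token
    a1 = assay.other_allele or "C"
    a2 = assay.tag_allele or "T"
    if not positive:
        return GenotypeCall(sample_id, assay.assay_id, (a1, a1)), SNV_CLASSES[0]
    if zygosity == "hom":
        return GenotypeCall(sample_id, assay.assay_id, (a2, a2)), SNV_CLASSES[2]
    return GenotypeCall(sample_id, assay.assay_id, (a1, a2)), SNV_CLASSES[1]


def simulate_cohort(config: SimConfig, panel: Panel | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort (reference typings, marker truth, calls)."""
    rng = np.random.default_rng(config.seed)
    target = parse_hla_allele(config.target)
    p = config.resolved_allele_frequency()
    assays = _assay_lookup(config, panel)

    n = config.n_samples
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    u = rng.random(n)
    # HWE genotype: 2 copies w.p. p^2, 1 w.p. 2p(1-p), else 0
    copies = np.where(u < p * p, 2, np.where(u < p * p + 2 * p * (1 - p), 1, 0))
    carrier = copies > 0

    references = tuple(
        _reference_for(sid, target, int(c), rng)
        for sid, c in zip(sample_ids, copies)
    )

    shared_u = rng.random(n)  # latent uniform for comonotone markers
    truth_rows = []
    calls: list[GenotypeCall] = []
    for spec in config.markers:
        assay = assays[spec.assay_id]
        if config.correlation == "comonotone":
            draw = shared_u
        else:
            draw = rng.random(n)
        p_pos = np.where(carrier, spec.sensitivity, 1.0 - spec.specificity)
        positive = draw < p_pos
        zyg_flip = rng.random(n) < config.zygosity_discordance_rate
        indet = rng.random(n) < config.indeterminate_rate
        for i, sid in enumerate(sample_ids):
            if positive[i]:
                base = "hom" if copies[i] >= 2 else "het"
                if zyg_flip[i]:
                    base = "het" if base == "hom" else "hom"
                zyg = "unknown" if assay.mode == "allele_specific" else base
            else:
                zyg = "none"
            call, class_label = _call_for(sid, assay, bool(positive[i]), zyg)
            if indet[i]:
                call = GenotypeCall(sid, assay.assay_id, (), INDETERMINATE)
            truth_rows.append(
                (sid, assay.assay_id, bool(positive[i]), zyg, class_label, bool(indet[i]))
            )
            calls.append(call)

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "carrier": carrier, "copies": copies}
    )
    marker_truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "assay_id", "true_positive", "zygosity",
                 "class_label", "indeterminate"],
    )
    return SimulatedCohort(config, references, samples, marker_truth, tuple(calls))


def simulate_fluorescence(
    marker_truth: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> list[FluorescencePoint]:
    """Emit one endpoint (FAM, VIC) well per marker-truth row, plus NTC wells.

    Every class label present in ``marker_truth`` must have a centroid in
    ``config.fluorescence.centroids``; clouds are isotropic Gaussians of SD
    ``sigma`` clipped at zero.
    """
    spec = config.fluorescence
    if spec is None:
        raise DataError("SimConfig.fluorescence is not set")
    emitted = set(marker_truth["class_label"].unique())
    missing = emitted - set(spec.centroids)
    if missing:
        raise DataError(f"no fluorescence centroid for class(es): {sorted(missing)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    points: list[FluorescencePoint] = []
    for row in marker_truth.itertuples(index=False):
        cx, cy = spec.centroids[row.class_label]
        fam = max(0.0, cx + rng.normal(0.0, spec.sigma)) if spec.sigma else cx
        vic = max(0.0, cy + rng.normal(0.0, spec.sigma)) if spec.sigma else cy
        points.append(FluorescencePoint(row.sample_id, row.assay_id, fam, vic))
    assay_ids = list(dict.fromkeys(marker_truth["assay_id"]))
    for aid in assay_ids:
        for j in range(spec.n_ntc):
            jitter = abs(rng.normal(0.0, spec.ntc_level * 0.25)) if spec.sigma else 0.0
            points.append(
                FluorescencePoint(
                    f"NTC{j + 1}", aid,
                    spec.ntc_level + jitter, spec.ntc_level + jitter, is_ntc=True,
                )
            )
    return points


# ---------------------------------------------------------------------------
# deterministic fixtures realising printed 2x2 tables

def fixture_from_confusion(
    t: ConfusionTable,
    target: HLAAllele | str,
    marker: str | Sequence[str],
    combinator: str = "SINGLE",
    panel: Panel | None = None,
    sample_prefix: str = "F",
) -> tuple[list[ReferenceTyping], list[GenotypeCall]]:
    """Build the minimal deterministic cohort whose evaluation reproduces ``t``.

    TP samples are single-copy carriers called positive, FP non-carriers
    called positive, FN carriers called negative, TN non-carriers called
    negative; ``t.n_indeterminate`` extra non-carriers get indeterminate
    calls.  For multi-assay ANY units, positives fire on the first assay
    only (exercising the either-assay-counts semantics); for ALL they fire
    on every assay.
    """
    target = parse_hla_allele(target) if isinstance(target, str) else target
    assay_ids = [marker] if isinstance(marker, str) else list(marker)
    pan = panel if panel is not None else default_panel()
    assays = []
    for aid in assay_ids:
        assays.append(
            pan.assays.get(aid)
            or SNVAssay(assay_id=aid, rsid=aid, tag_allele="T", other_allele="C")
        )

    fillers = [
        f for f in FILLER_ALLELES.get(target.locus, ("X*99:99",))
        if parse_hla_allele(f).two_field != target.two_field
    ]
    f1, f2 = parse_hla_allele(fillers[0]), parse_hla_allele(fillers[1 % len(fillers)])

    refs: list[ReferenceTyping] = []
    calls: list[GenotypeCall] = []
    counter = 0

    def add(carrier: bool, result: str) -> None:
        nonlocal counter
        counter += 1
        sid = f"{sample_prefix}{counter:04d}"
        alleles = (target, f1) if carrier else (f1, f2)
        refs.append(ReferenceTyping(sid, target.locus, alleles))
        for k, assay in enumerate(assays):
            if result == INDETERMINATE:
                calls.append(GenotypeCall(sid, assay.assay_id, (), INDETERMINATE))
                continue
            if result == "positive":
                fire = True if combinator in ("SINGLE", "ALL") else k == 0
            else:
                fire = False
            call, _ = _call_for(sid, assay, fire, "het" if fire else "none")
            calls.append(call)

    for _ in range(t.tp):
        add(True, "positive")
    for _ in range(t.fp):
        add(False, "positive")
    for _ in range(t.fn):
        add(True, "negative")
    for _ in range(t.tn):
        add(False, "negative")
    for _ in range(t.n_indeterminate):
        add(False, INDETERMINATE)
    return refs, calls


def crossed_two_marker_fixture(
    tp: int,
    fp_a_only: int,
    fp_b_only: int,
    tn_both: int,
    target: HLAAllele | str,
    assay_a: str,
    assay_b: str,
    panel: Panel | None = None,
    sample_prefix: str = "X",
) -> tuple[list[ReferenceTyping], list[GenotypeCall]]:
    """Cohort where two markers over-call on disjoint non-carrier subsets.

    Carriers are positive on both assays; ``fp_a_only``/``fp_b_only``
    non-carriers are positive on exactly one.  Evaluated per marker this
    yields each marker's own false positives; evaluated under an ALL rule
    the false positives vanish while true positives are preserved.
    """
    target = parse_hla_allele(target) if isinstance(target, str) else target
    pan = panel if panel is not None else default_panel()
    assays = {
        aid: pan.assays.get(aid)
        or SNVAssay(assay_id=aid, rsid=aid, tag_allele="T", other_allele="C")
        for aid in (assay_a, assay_b)
    }
    fillers = [
        f for f in FILLER_ALLELES.get(target.locus, ("X*99:99",))
        if parse_hla_allele(f).two_field != target.two_field
    ]
    f1, f2 = parse_hla_allele(fillers[0]), parse_hla_allele(fillers[1 % len(fillers)])

    refs: list[ReferenceTyping] = []
    calls: list[GenotypeCall] = []
    counter = 0

    def add(carrier: bool, pos_a: bool, pos_b: bool) -> None:
        nonlocal counter
        counter += 1
        sid = f"{sample_prefix}{counter:04d}"
        alleles = (target, f1) if carrier else (f1, f2)
        refs.append(ReferenceTyping(sid, target.locus, alleles))
        for aid, fire in ((assay_a, pos_a), (assay_b, pos_b)):
            call, _ = _call_for(sid, assays[aid], fire, "het" if fire else "none")
            calls.append(call)

    for _ in range(tp):
        add(True, True, True)
    for _ in range(fp_a_only):
        add(False, True, False)
    for _ in range(fp_b_only):
        add(False, False, True)
    for _ in range(tn_both):
        add(False, False, False)
    return refs, calls
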