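"""Allelic-discrimination cluster calling from endpoint fluorescence.

Endpoint TaqMan genotyping yields one (FAM, VIC) intensity pair per well;
samples of the same genotype form clusters in this plane.  Instrument
software draws and labels these clusters; this module provides a
reproducible equivalent: channels are min-max normalised, class centroids
are seeded at their canonical positions and refined by a deterministic
k-means loop, and wells are rejected as indeterminate when they sit inside
the no-template-control (NTC) envelope or too close to a class boundary.

Two assay modes:

* ``snv_tag`` — three classes: homozygous allele-1 (FAM axis), heterozygous
  (diagonal), homozygous allele-2 (VIC axis).  Allele 1 is the assay's
  ``other_allele`` (FAM reporter), allele 2 the ``tag_allele`` (VIC).
* ``allele_specific`` — two classes read against an internal reference
  amplification on FAM (e.g. ß-Globin): ``negative`` (reference only) and
  ``positive`` (reference + target VIC signal).  A well whose reference
  channel fails is a failed reaction, hence indeterminate regardless of the
  target channel.

Boundary rejection uses the relative margin (d2 - d1)/(d2 + d1) between the
two nearest centroids, so it is invariant to common rescaling of both
channels; a larger ``undetermined_threshold`` rejects more wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ClusterError
from .genotype_io import DETERMINATE, INDETERMINATE, GenotypeCall
from .panel import SNVAssay

__all__ = [
    "FluorescencePoint",
    "ClusterOptions",
    "ClusterModel",
    "fit_cluster_model",
    "call_allelic_discrimination",
    "read_fluorescence_table",
    "plot_discrimination",
]

SNV_CLASSES = ("homo_allele1", "het", "homo_allele2")
AS_CLASSES = ("negative", "positive")

# canonical centroid priors on the min-max normalised [0,1]^2 plane
_SNV_PRIORS = {"homo_allele1": (1.0, 0.05), "het": (0.75, 0.75), "homo_allele2": (0.05, 1.0)}
_AS_PRIORS = {"negative": (1.0, 0.05), "positive": (1.0, 1.0)}


@dataclass(frozen=True)
class FluorescencePoint:
    """Endpoint fluorescence of one well (baseline-subtracted if available)."""

    sample_id: str
    assay_id: str
    fam: float
    vic: float
    is_ntc: bool = False

    def __post_init__(self) -> None:
        for ch, v in (("fam", self.fam), ("vic", self.vic)):
            if not math.isfinite(v) or v < 0:
                raise ClusterError(
                    f"{self.sample_id}/{self.assay_id}: {ch} signal must be finite "
                    f"and >= 0, got {v!r}"
                )


@dataclass(frozen=True)
class ClusterOptions:
    """Tunables for fitting and calling.

    undetermined_threshold : relative margin below which a well is rejected
        (0 disables boundary rejection; 1 rejects everything ambiguous).
    ntc_margin : multiplicative head-room above the NTC envelope.
    ntc_floor : fallback absolute floor (normalised units) when no NTC wells
        are provided.
    seed : kept for API stability; the refinement is deterministic.
    """

    undetermined_threshold: float = 0.33
    ntc_margin: float = 1.2
    ntc_floor: float = 0.08
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.undetermined_threshold < 1:
            raise ClusterError("undetermined_threshold must be in [0, 1)")


@dataclass(frozen=True)
class ClusterModel:
    """Fitted per-assay cluster model in normalised (fam, vic) space."""

    assay_id: str
    mode: str
    classes: tuple[str, ...]
    centroids: dict
    dispersion: dict
    norm: tuple[float, float, float, float]  # fam_min, fam_range, vic_min, vic_range
    floor: tuple[float, float]
    undetermined_threshold: float
    separation: float = float("nan")

    def normalise(self, fam, vic) -> tuple[np.ndarray, np.ndarray]:
        fmin, frange, vmin, vrange = self.norm
        return (np.asarray(fam) - fmin) / frange, (np.asarray(vic) - vmin) / vrange

    def classify(self, point: FluorescencePoint) -> str:
        """Class label or ``"indeterminate"`` for one well."""
        x, y = self.normalise(point.fam, point.vic)
        if self.mode == "allele_specific":
            if x <= self.floor[0]:  # reference channel failed to amplify
                return INDETERMINATE
        if x <= self.floor[0] and y <= self.floor[1]:  # inside NTC envelope
            return INDETERMINATE
        d = {
            c: math.hypot(x - cx, y - cy) for c, (cx, cy) in self.centroids.items()
        }
        ranked = sorted(d, key=lambda c: (d[c], self.classes.index(c)))
        best = ranked[0]
        if len(ranked) > 1 and self.undetermined_threshold > 0:
            d1, d2 = d[best], d[ranked[1]]
            if d1 + d2 > 0 and (d2 - d1) / (d2 + d1) < self.undetermined_threshold:
                return INDETERMINATE
        return best


def _prepare(points: Sequence[FluorescencePoint], assay: SNVAssay):
    if not points:
        raise ClusterError(f"assay {assay.assay_id}: empty fluorescence input")
    ids = {p.assay_id for p in points}
    if ids != {assay.assay_id}:
        raise ClusterError(
            f"fluorescence points mix assays {sorted(ids)}; expected only {assay.assay_id}"
        )
    data = [p for p in points if not p.is_ntc]
    ntc = [p for p in points if p.is_ntc]
    if not data:
        raise ClusterError(f"assay {assay.assay_id}: all points are NTC wells")
    return data, ntc


def fit_cluster_model(
    points: Sequence[FluorescencePoint],
    assay: SNVAssay,
    options: ClusterOptions | None = None,
) -> ClusterModel:
    """Fit the per-assay cluster model by seeded, deterministic k-means.

    Centroids start at canonical genotype positions and are refined on the
    min-max normalised data; a class left empty keeps its prior position, so
    degenerate cohorts (e.g. no positives) are handled gracefully.  Raises
    :class:`ClusterError` when the data carry no spread at all.
    """
    opts = options or ClusterOptions()
    data, ntc = _prepare(points, assay)
    mode = assay.mode
    classes = AS_CLASSES if mode == "allele_specific" else SNV_CLASSES
    min_pts = 2 if mode == "allele_specific" else max(3, len(classes))
    if len(data) < min_pts:
        raise ClusterError(
            f"assay {assay.assay_id}: need >= {min_pts} non-NTC points, got {len(data)}"
        )

    fam = np.array([p.fam for p in data], dtype=float)
    vic = np.array([p.vic for p in data], dtype=float)
    if float(fam.max()) == float(fam.min()) and float(vic.max()) == float(vic.min()):
        raise ClusterError(
            f"assay {assay.assay_id}: degenerate fluorescence data (all points identical)"
        )
    # One zero-anchored scale shared by both channels: invariant under common
    # rescaling, and — unlike per-channel min-max — it does not stretch pure
    # noise into the unit square when a genotype class is absent.
    scale = float(max(fam.max(), vic.max()))
    if scale <= 0:
        raise ClusterError(
            f"assay {assay.assay_id}: degenerate fluorescence data (no signal)"
        )
    fmin = vmin = 0.0
    frange = vrange = scale
    X = np.column_stack((fam / scale, vic / scale))

    priors = _AS_PRIORS if mode == "allele_specific" else _SNV_PRIORS
    centroids = np.array([priors[c] for c in classes], dtype=float)
    labels = np.zeros(len(X), dtype=int)
    for _ in range(opts.max_iter):
        dists = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
        new_labels = dists.argmin(axis=1)
        new_centroids = centroids.copy()
        for k in range(len(classes)):
            members = X[new_labels == k]
            if len(members):
                new_centroids[k] = members.mean(axis=0)
        if np.array_equal(new_labels, labels) and np.allclose(new_centroids, centroids):
            break
        labels, centroids = new_labels, new_centroids

    dispersion = {}
    for k, c in enumerate(classes):
        members = X[labels == k]
        dispersion[c] = (
            float(np.linalg.norm(members - centroids[k], axis=1).mean())
            if len(members)
            else float("nan")
        )

    # NTC envelope floor (normalised units)
    if ntc:
        nf = (np.array([p.fam for p in ntc]) - fmin) / frange
        nv = (np.array([p.vic for p in ntc]) - vmin) / vrange
        floor = (
            max(float(nf.max()) * opts.ntc_margin, opts.ntc_floor),
            max(float(nv.max()) * opts.ntc_margin, opts.ntc_floor),
        )
    else:
        floor = (opts.ntc_floor, opts.ntc_floor)

    separation = float("nan")
    if len(set(labels.tolist())) > 1:
        from sklearn.metrics import silhouette_score

        try:
            separation = float(silhouette_score(X, labels))
        except ValueError:  # pragma: no cover - tiny degenerate classes
            pass

    return ClusterModel(
        assay_id=assay.assay_id,
        mode=mode,
        classes=tuple(classes),
        centroids={c: tuple(centroids[k]) for k, c in enumerate(classes)},
        dispersion=dispersion,
        norm=(fmin, frange, vmin, vrange),
        floor=floor,
        undetermined_threshold=opts.undetermined_threshold,
        separation=separation,
    )


def _class_to_call(sample_id: str, assay: SNVAssay, label: str) -> GenotypeCall:
    if label == INDETERMINATE:
        return GenotypeCall(sample_id, assay.assay_id, (), INDETERMINATE)
    if assay.mode == "allele_specific":
        return GenotypeCall(sample_id, assay.assay_id, (label,))
    a1 = assay.other_allele or "allele1"
    a2 = assay.tag_allele or "allele2"
    alleles = {
        "homo_allele1": (a1, a1),
        "het": (a1, a2),
        "homo_allele2": (a2, a2),
    }[label]
    return GenotypeCall(sample_id, assay.assay_id, alleles)


def call_allelic_discrimination(
    points: Sequence[FluorescencePoint],
    assay: SNVAssay,
    options: ClusterOptions | None = None,
    model: ClusterModel | None = None,
) -> list[GenotypeCall]:
    """Fit (unless a model is given) and call every non-NTC well.

    Deterministic and input-order independent; NTC wells are never called.
    """
    if model is None:
        model = fit_cluster_model(points, assay, options)
    data, _ = _prepare(points, assay)
    return [_class_to_call(p.sample_id, assay, model.classify(p)) for p in data]


# ---------------------------------------------------------------------------
# I/O and plotting

def read_fluorescence_table(source, delimiter: str | None = None) -> list[FluorescencePoint]:
    """Read wells from delimited text: sample_id, assay_id, fam, vic[, is_ntc]."""
    import pandas as pd

    df = pd.read_csv(source, sep=delimiter, engine="python", dtype=str,
                     keep_default_na=False)
    required = {"sample_id", "assay_id", "fam", "vic"}
    missing = required - set(df.columns)
    if missing:
        raise ClusterError(f"fluorescence table missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        is_ntc = str(getattr(row, "is_ntc", "")).strip().lower() in {"1", "true", "yes"}
        out.append(
            FluorescencePoint(row.sample_id, row.assay_id,
                              float(row.fam), float(row.vic), is_ntc)
        )
    return out


def plot_discrimination(
    points: Sequence[FluorescencePoint],
    calls: Sequence[GenotypeCall] | None = None,
    model: ClusterModel | None = None,
    ax=None,
    title: str = "",
):
    """Scatter the discrimination plane, coloured by call class; returns the axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    by_sample = {}
    if calls:
        for c in calls:
            key = "indeterminate" if not c.is_determinate else "/".join(c.alleles)
            by_sample[c.sample_id] = key
    groups: dict[str, list[FluorescencePoint]] = {}
    for p in points:
        label = "NTC" if p.is_ntc else by_sample.get(p.sample_id, "well")
        groups.setdefault(label, []).append(p)
    for label, pts in sorted(groups.items()):
        ax.scatter([p.fam for p in pts], [p.vic for p in pts], s=18, label=label)
    if model is not None:
        fmin, frange, vmin, vrange = model.norm
        for cname, (cx, cy) in model.centroids.items():
            ax.plot(cx * frange + fmin, cy * vrange + vmin, "kx", ms=10)
    ax.set_xlabel("FAM signal")
    ax.set_ylabel("VIC signal")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
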