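"""Iterative k-means segmentation with Kolmogorov–Smirnov termination.

The segmenter partitions a prepared scalar image ℬ (ROI values plus a
background sentinel) into k clusters with restarted Lloyd k-means
(k-means++ initialization), relabels clusters so centroids ascend, and
iterates over k:

* k starts at 3: cluster 1 is the background (sentinel), cluster 2 the
  tumor complement, cluster 3 the provisional tumor region T̂;
* at each k, T̂ is the highest-valued cluster and T̂ᶜ the union of the
  intermediate clusters (the ROI minus T̂); the pixel values under each
  mask are extracted from the image;
* for k > 3 two two-sample KS tests compare the current T̂ and T̂ᶜ value
  samples against the previous iteration's; the loop stops the first
  time neither null hypothesis ("same distribution") is rejected at the
  1% significance level.

The final clusters map to tissue types by ascending value: background,
fatty, transition (clusters 3–4), fibroglandular (clusters 5..max−1),
and malignant (the top cluster).  No prior knowledge of the dielectric
ranges of the tissues, nor a pre-selected cluster count, is required —
the statistical termination chooses k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import special
from sklearn.cluster import KMeans

from .io import COMPONENTS, PermittivityImage, component_images
from .roi import DEFAULT_SENTINEL, PreparedField, RegionMask, prepare_field

__all__ = [
    "Tissue",
    "TissueSegmentation",
    "Ecdf",
    "ecdf",
    "KSTestResult",
    "ks_two_sample",
    "ClusterLabeling",
    "cluster_once",
    "IterationRecord",
    "SegmentationHistory",
    "ConvergenceError",
    "iterate_segmentation",
    "map_clusters",
    "SegmentationParams",
    "segment_components",
]


class Tissue(IntEnum):
    """Tissue categories of the segmentation output.

    ``SKIN`` appears only in phantom ground truth; the segmenter treats
    skin and immersion medium as background (they lie outside the ROI).
    """

    BACKGROUND = 0
    FATTY = 1
    TRANSITION = 2
    FIBROGLANDULAR = 3
    MALIGNANT = 4
    SKIN = 5


@dataclass(frozen=True)
class TissueSegmentation:
    """Categorical tissue map over the grid."""

    labels: np.ndarray  # 2D array of Tissue codes
    source_component: str = "real"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("tissue labels must be 2D")
        valid = np.array([t.value for t in Tissue])
        if not np.isin(arr, valid).all():
            raise ValueError("unknown tissue code in labels")
        object.__setattr__(self, "labels", arr.astype(np.int8))

    def mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)


# ---------------------------------------------------------------------------
# Empirical distribution function and the two-sample KS test
# ---------------------------------------------------------------------------

class Ecdf:
    """Right-continuous empirical distribution function of a sample."""

    def __init__(self, sample: Sequence[float]):
        arr = np.asarray(sample, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("ECDF requires a nonempty sample")
        self._sorted = np.sort(arr)
        self.n = arr.size
        self.support = np.unique(self._sorted)
        self.fractions = (
            np.searchsorted(self._sorted, self.support, side="right") / self.n
        )

    def __call__(self, x) -> np.ndarray | float:
        q = np.asarray(x, dtype=float)
        out = np.searchsorted(self._sorted, q, side="right") / self.n
        return float(out) if np.isscalar(x) else out


def ecdf(sample: Sequence[float]) -> Ecdf:
    """Empirical CDF: E(x) = (#sample ≤ x) / n."""
    return Ecdf(sample)


@dataclass(frozen=True)
class KSTestResult:
    """Two-sample Kolmogorov–Smirnov test outcome."""

    statistic: float
    p_value: float
    rejected: bool
    alpha: float
    n1: int
    n2: int


def ks_two_sample(a: Sequence[float], b: Sequence[float],
                  alpha: float = 0.01) -> KSTestResult:
    """Two-sample KS test of H0: both samples share one distribution.

    The statistic is the supremum difference of the two empirical CDFs,
    attained on the pooled sample support.  The p-value uses the
    asymptotic Kolmogorov distribution with effective sample size
    n1·n2/(n1+n2); the pixel samples compared here number in the
    thousands, where the asymptotic approximation is standard.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two nonempty samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate([a_sorted, b_sorted])
    fa = np.searchsorted(a_sorted, pooled, side="right") / a.size
    fb = np.searchsorted(b_sorted, pooled, side="right") / b.size
    statistic = float(np.max(np.abs(fa - fb)))
    en = a.size * b.size / (a.size + b.size)
    p_value = float(special.kolmogorov(np.sqrt(en) * statistic))
    return KSTestResult(
        statistic=statistic,
        p_value=p_value,
        rejected=bool(p_value < alpha),
        alpha=alpha,
        n1=int(a.size),
        n2=int(b.size),
    )


# ---------------------------------------------------------------------------
# Restarted k-means with ascending-centroid relabeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterLabeling:
    """k-means result with labels 1..k ordered by ascending centroid value."""

    labels: np.ndarray         # 2D int array, values 1..k
    centroids: np.ndarray      # shape (k,), sorted ascending
    k: int
    objective: float           # within-cluster sum of squares of the kept restart
    restart_objectives: np.ndarray  # objective of every restart

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _sub_seeds(seed: int, n: int, salt: tuple[int, ...] = ()) -> np.ndarray:
    """Deterministic 31-bit sub-seeds derived from a master seed."""
    ss = np.random.SeedSequence((int(seed),) + tuple(int(s) for s in salt))
    return ss.generate_state(n) % (2 ** 31 - 1)


def cluster_once(field: PreparedField, k: int, restarts: int = 10,
                 seed: int = 0) -> ClusterLabeling:
    """Cluster the scalar values of ℬ into k clusters, best of ``restarts``.

    Each restart runs Lloyd's algorithm from a fresh k-means++
    initialization with its own sub-seed; the restart with the smallest
    within-cluster sum of squares is kept.  Labels are then renumbered so
    centroids ascend, which puts every sentinel (background) element in
    cluster 1.
    """
    if k < 3:
        raise ValueError("k must be at least 3 (background, complement, tumor)")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    data = field.values.reshape(-1, 1)
    n_distinct = np.unique(data).size
    if k > n_distinct:
        raise ValueError(
            f"unclusterable: k={k} exceeds the {n_distinct} distinct values"
        )
    best = None
    objectives = np.empty(restarts, dtype=float)
    for i, sub_seed in enumerate(_sub_seeds(seed, restarts)):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    algorithm="lloyd", random_state=int(sub_seed))
        km.fit(data)
        objectives[i] = km.inertia_
        if best is None or km.inertia_ < best.inertia_:
            best = km
    # Relabel so centroids ascend; stable sort keeps a deterministic order
    # for exactly tied centroids.
    order = np.argsort(best.cluster_centers_.ravel(), kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    labels = rank[best.labels_].reshape(field.values.shape)
    centroids = best.cluster_centers_.ravel()[order]

    background = ~field.roi_mask.as_bool()
    if background.any() and not np.array_equal(labels == 1, background):
        raise RuntimeError(
            "background conservation violated: sentinel elements do not "
            "form exactly the lowest cluster"
        )
    return ClusterLabeling(
        labels=labels,
        centroids=centroids,
        k=k,
        objective=float(best.inertia_),
        restart_objectives=objectives,
    )


# ---------------------------------------------------------------------------
# KS-terminated iteration over k
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IterationRecord:
    """State after one clustering pass at a given k."""

    k: int
    labeling: ClusterLabeling
    tumor_mask: np.ndarray        # T̂ = top cluster
    complement_mask: np.ndarray   # T̂ᶜ = clusters 2..k−1
    tumor_values: np.ndarray      # v_t = T̂ ⊙ ℐ
    complement_values: np.ndarray  # v_c = T̂ᶜ ⊙ ℐ
    ks_tumor: KSTestResult | None = None
    ks_complement: KSTestResult | None = None


@dataclass
class SegmentationHistory:
    """Per-iteration records of the KS-terminated refinement."""

    records: list[IterationRecord] = dataclass_field(default_factory=list)

    def append(self, record: IterationRecord) -> None:
        if not self.records:
            if record.k != 3:
                raise ValueError("history must start at k = 3")
            if record.ks_tumor is not None or record.ks_complement is not None:
                raise ValueError("the k = 3 record carries no KS results")
        elif record.k != self.records[-1].k + 1:
            raise ValueError("history k must increase strictly by 1")
        self.records.append(record)

    @property
    def final_k(self) -> int:
        return self.records[-1].k

    def terminated_cleanly(self) -> bool:
        last = self.records[-1]
        return (
            last.ks_tumor is not None
            and not last.ks_tumor.rejected
            and not last.ks_complement.rejected
        )

    def summary(self) -> list[dict]:
        """JSON-friendly per-iteration log (k, objective, KS stats/p/decisions)."""
        out = []
        for rec in self.records:
            row = {
                "k": rec.k,
                "objective": rec.labeling.objective,
                "restart_objectives": rec.labeling.restart_objectives.tolist(),
                "n_tumor": int(rec.tumor_values.size),
                "n_complement": int(rec.complement_values.size),
            }
            for name, ks in (("tumor", rec.ks_tumor),
                             ("complement", rec.ks_complement)):
                if ks is not None:
                    row[f"ks_{name}_statistic"] = ks.statistic
                    row[f"ks_{name}_p_value"] = ks.p_value
                    row[f"ks_{name}_rejected"] = ks.rejected
            out.append(row)
        return out


class ConvergenceError(RuntimeError):
    """Raised when k reaches k_max without KS termination; carries history."""

    def __init__(self, message: str, history: SegmentationHistory):
        super().__init__(message)
        self.history = history


def _record_for(field: PreparedField, labeling: ClusterLabeling,
                ks_t: KSTestResult | None, ks_c: KSTestResult | None
                ) -> IterationRecord:
    k = labeling.k
    tumor = labeling.labels == k
    complement = (labeling.labels >= 2) & (labeling.labels <= k - 1)
    if not tumor.any():
        raise RuntimeError(f"empty tumor cluster at k={k}")
    if not complement.any():
        raise RuntimeError(f"empty tumor-complement at k={k}")
    return IterationRecord(
        k=k,
        labeling=labeling,
        tumor_mask=tumor,
        complement_mask=complement,
        tumor_values=field.values[tumor],
        complement_values=field.values[complement],
        ks_tumor=ks_t,
        ks_complement=ks_c,
    )


def iterate_segmentation(field: PreparedField, alpha: float = 0.01,
                         restarts: int = 10, seed: int = 0,
                         k_max: int = 20
                         ) -> tuple[ClusterLabeling, SegmentationHistory]:
    """Refine the cluster count until the KS tests stop rejecting.

    Starting at k = 3, each iteration increments k, reclusters, updates
    T̂ (top cluster) and T̂ᶜ (intermediate clusters), and for k > 3 tests
    whether the value samples under both masks are distributed as in the
    previous iteration.  Termination occurs the first time neither null
    hypothesis is rejected at level ``alpha``.

    Raises
    ------
    ConvergenceError
        If k reaches ``k_max`` without termination (history attached).
    RuntimeError
        If a tumor or complement mask comes out empty at any k.
    """
    history = SegmentationHistory()
    labeling = cluster_once(field, k=3, restarts=restarts,
                            seed=int(_sub_seeds(seed, 1, salt=(3,))[0]))
    record = _record_for(field, labeling, None, None)
    history.append(record)
    prev = record
    for k in range(4, k_max + 1):
        labeling = cluster_once(field, k=k, restarts=restarts,
                                seed=int(_sub_seeds(seed, 1, salt=(k,))[0]))
        tumor = labeling.labels == k
        complement = (labeling.labels >= 2) & (labeling.labels <= k - 1)
        if not tumor.any() or not complement.any():
            raise RuntimeError(f"empty tumor or complement mask at k={k}")
        v_t = field.values[tumor]
        v_c = field.values[complement]
        ks_t = ks_two_sample(v_t, prev.tumor_values, alpha=alpha)
        ks_c = ks_two_sample(v_c, prev.complement_values, alpha=alpha)
        record = _record_for(field, labeling, ks_t, ks_c)
        history.append(record)
        prev = record
        if not ks_t.rejected and not ks_c.rejected:
            return labeling, history
    raise ConvergenceError(
        f"no KS termination by k_max={k_max}", history
    )


# ---------------------------------------------------------------------------
# Cluster → tissue mapping
# ---------------------------------------------------------------------------

def map_clusters(labeling: ClusterLabeling,
                 source_component: str = "real") -> TissueSegmentation:
    """Map ascending-value clusters to tissue types.

    cluster 1 → background, 2 → fatty, 3–4 → transition,
    5..max(k)−1 → fibroglandular, max(k) → malignant.  When the
    refinement stopped after a single iteration (max(k) = 4) the three
    interior clusters identify fatty, fibroglandular, and malignant
    tissue instead.  max(k) = 5 leaves the fibroglandular set empty by
    construction; a warning flags it.
    """
    kmax = labeling.k
    if kmax < 4:
        raise ValueError("cluster → tissue mapping requires max(k) >= 4")
    lut = np.empty(kmax + 1, dtype=np.int8)
    lut[0] = Tissue.BACKGROUND  # unused slot
    if kmax == 4:
        lut[1] = Tissue.BACKGROUND
        lut[2] = Tissue.FATTY
        lut[3] = Tissue.FIBROGLANDULAR
        lut[4] = Tissue.MALIGNANT
    else:
        lut[1] = Tissue.BACKGROUND
        lut[2] = Tissue.FATTY
        lut[3] = Tissue.TRANSITION
        lut[4] = Tissue.TRANSITION
        for c in range(5, kmax):
            lut[c] = Tissue.FIBROGLANDULAR
        lut[kmax] = Tissue.MALIGNANT
        if kmax == 5:
            warnings.warn(
                "max(k) = 5 leaves the fibroglandular set empty "
                "(clusters 3-4 map to transition, cluster 5 to malignant)",
                stacklevel=2,
            )
    return TissueSegmentation(labels=lut[labeling.labels],
                              source_component=source_component)


# ---------------------------------------------------------------------------
# Whole-image pipeline per component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the full segmentation pipeline."""

    alpha: float = 0.01       # KS significance level
    restarts: int = 10        # k-means restarts d per k
    seed: int = 0
    k_max: int = 20
    sentinel: float = DEFAULT_SENTINEL
    components: tuple[str, ...] = COMPONENTS


def segment_components(image: PermittivityImage, roi: RegionMask,
                       params: SegmentationParams = SegmentationParams()
                       ) -> dict[str, tuple[TissueSegmentation, SegmentationHistory]]:
    """Run the full pipeline independently on Re{ϵ}, |Im{ϵ}|, and |ϵ|.

    Returns a map component → (tissue segmentation, iteration history).
    """
    if image.shape != roi.shape:
        raise ValueError("image and ROI shapes must match")
    comps = component_images(image)
    out: dict[str, tuple[TissueSegmentation, SegmentationHistory]] = {}
    for idx, name in enumerate(params.components):
        if name not in comps:
            raise ValueError(f"unknown component {name!r}")
        field = prepare_field(comps[name], roi, sentinel=params.sentinel)
        comp_seed = int(_sub_seeds(params.seed, 1, salt=(1000 + idx,))[0])
        labeling, history = iterate_segmentation(
            field, alpha=params.alpha, restarts=params.restarts,
            seed=comp_seed, k_max=params.k_max,
        )
        out[name] = (map_clusters(labeling, source_component=name), history)
    return out
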