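"""The visual codebook: patch embeddings, k-means key features, impact scores.

Tissue patches are embedded, the embeddings are clustered with k-means into
``k`` "key features" (100 by default), every patch is assigned to its
nearest centroid, and each sample is summarised by its composition vector —
the fraction of its tissue patches falling in each cluster.  Each cluster
additionally carries an *impact score* in [0, 1]: the (smoothed) fraction of
its patches that came from outcome-positive patients, with 0.5 neutral.
Clusters are displayed at size ``|0.5 - impact| + 2.5`` so the most
outcome-informative features render largest.

The default embedding is a handcrafted descriptor (colour-channel moments,
a gradient-orientation histogram and radial power-spectrum bins); a
supervised variant appends a linear-discriminant coordinate trained on
patch-level outcome labels.  Any callable mapping a patch to a fixed-length
vector can stand in via :class:`EmbeddingBackend`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .tiling import PatchSet

__all__ = [
    "EmbeddingBackend",
    "Codebook",
    "CompositionVector",
    "patch_descriptor",
    "fit_default_backend",
    "fit_codebook",
    "assign",
    "compose",
    "impact_scores",
    "display_size",
    "representative_patches",
    "feature_map",
]

_N_ORIENT_BINS = 8
_N_RADIAL_BINS = 6


def patch_descriptor(patch: np.ndarray) -> np.ndarray:
    """Handcrafted patch embedding: colour moments + gradients + spectrum.

    Blocks: per-channel mean and standard deviation (6 values for RGB),
    a gradient-orientation histogram over 8 bins weighted by gradient
    magnitude (all-zero for constant patches), and 6 radial bins of the
    grey-level power spectrum (DC excluded, L1-normalised).
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim == 2:
        p = p[..., None]
    if p.max() > 1.5:  # uint8 range
        p = p / 255.0
    n_ch = p.shape[2]
    moments = np.concatenate([[p[..., c].mean(), p[..., c].std()]
                              for c in range(n_ch)])
    if n_ch < 3:
        moments = np.concatenate([moments, np.zeros(6 - 2 * n_ch)])

    grey = p.mean(axis=2)
    gy, gx = np.gradient(grey)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % np.pi  # orientation, not direction
    hist = np.zeros(_N_ORIENT_BINS)
    if mag.sum() > 0:
        bins = np.minimum((ang / np.pi * _N_ORIENT_BINS).astype(int),
                          _N_ORIENT_BINS - 1)
        np.add.at(hist, bins.ravel(), mag.ravel())
        hist /= hist.sum()

    spec = np.abs(np.fft.fftshift(np.fft.fft2(grey - grey.mean()))) ** 2
    h, w = grey.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h / 2, xx - w / 2)
    r_max = r.max() or 1.0
    radial = np.zeros(_N_RADIAL_BINS)
    rbin = np.minimum((r / r_max * _N_RADIAL_BINS).astype(int),
                      _N_RADIAL_BINS - 1)
    np.add.at(radial, rbin.ravel(), spec.ravel())
    total = radial.sum()
    if total > 0:
        radial /= total
    return np.concatenate([moments, hist, radial])


@dataclass
class EmbeddingBackend:
    """A deterministic patch -> vector map with a declared dimensionality."""

    name: str
    dim: int
    transform: Callable[[np.ndarray], np.ndarray]

    def embed(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        out = np.vstack([np.asarray(self.transform(p), dtype=float)
                         for p in patches])
        if out.shape[1] != self.dim:
            raise ValueError("backend produced wrong dimensionality")
        if not np.all(np.isfinite(out)):
            raise ValueError("backend produced non-finite embeddings")
        return out


def fit_default_backend(patches: Sequence[np.ndarray],
                        labels: Sequence[int] | None = None) -> EmbeddingBackend:
    """Build the default descriptor backend, optionally supervised.

    With ``labels`` (patch-level binary outcome), a linear discriminant is
    fitted on the descriptors and its coordinate appended, miniaturising the
    idea of a penultimate representation trained to separate outcome
    classes.
    """
    if len(patches) < 1:
        raise ValueError("need at least one patch")
    base_dim = len(patch_descriptor(patches[0]))
    if labels is None:
        return EmbeddingBackend("descriptor", base_dim, patch_descriptor)

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("supervised backend requires both outcome classes")
    X = np.vstack([patch_descriptor(p) for p in patches])
    lda = LinearDiscriminantAnalysis(n_components=1)
    lda.fit(X, y)

    def transform(patch: np.ndarray) -> np.ndarray:
        d = patch_descriptor(patch)
        return np.concatenate([d, lda.transform(d[None, :])[0]])

    return EmbeddingBackend("descriptor+lda", base_dim + 1, transform)


@dataclass
class Codebook:
    """Fitted k-means centroids over patch embeddings, plus impact scores."""

    k: int
    centroids: np.ndarray
    backend_name: str = "descriptor"
    fit_seed: int = 0
    impact: np.ndarray | None = None
    inertia: float = float("nan")

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise ValueError("codebook needs k >= 2")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.impact is not None:
            self.impact = np.asarray(self.impact, dtype=float)
            if np.any((self.impact < 0) | (self.impact > 1)):
                raise ValueError("impact scores must lie in [0, 1]")

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def save(self, stem: str | Path) -> None:
        """Persist as ``<stem>.json`` (metadata) + ``<stem>_centroids.csv``."""
        stem = Path(stem)
        meta = {
            "k": self.k,
            "backend_name": self.backend_name,
            "fit_seed": self.fit_seed,
            "inertia": self.inertia,
            "impact": None if self.impact is None
            else [float(v) for v in self.impact],
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        pd.DataFrame(self.centroids).to_csv(
            stem.parent / f"{stem.name}_centroids.csv", index=False)

    @classmethod
    def load(cls, stem: str | Path) -> "Codebook":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        centroids = pd.read_csv(
            stem.parent / f"{stem.name}_centroids.csv").to_numpy(float)
        impact = meta["impact"]
        return cls(k=meta["k"], centroids=centroids,
                   backend_name=meta["backend_name"],
                   fit_seed=meta["fit_seed"],
                   impact=None if impact is None else np.asarray(impact),
                   inertia=meta["inertia"])


@dataclass
class CompositionVector:
    """Per-sample fractions of tissue patches in each cluster (sums to 1)."""

    sample_id: str
    fractions: np.ndarray
    n_tissue_patches: int

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_tissue_patches < 1:
            raise ValueError("composition requires at least one tissue patch")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1) > 1e-8:
            raise ValueError("fractions must be nonnegative and sum to 1")


def fit_codebook(embeddings: np.ndarray, k: int = 100, seed: int = 0,
                 n_restarts: int = 4) -> Codebook:
    """k-means++ codebook over patch embeddings, best of ``n_restarts``."""
    X = np.asarray(embeddings, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} embeddings, got {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    km.fit(X)
    return Codebook(k=k, centroids=km.cluster_centers_, fit_seed=seed,
                    inertia=float(km.inertia_))


def assign(codebook: Codebook, embeddings: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment (Euclidean; ties go to the lowest index)."""
    X = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if X.shape[1] != codebook.dim:
        raise ValueError(
            f"embedding dim {X.shape[1]} != codebook dim {codebook.dim}")
    d2 = ((X[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin returns the first (lowest) index


def compose(assignments: np.ndarray, k: int,
            tissue_mask: np.ndarray | None = None,
            sample_id: str = "sample") -> CompositionVector:
    """Tally tissue-patch assignments into a composition vector.

    Background patches (``tissue_mask`` False) are excluded before
    normalisation, matching the convention that totals count only patches
    with histological content.
    """
    a = np.asarray(assignments, dtype=int)
    if tissue_mask is not None:
        a = a[np.asarray(tissue_mask, dtype=bool)]
    if a.size == 0:
        raise ValueError(f"sample {sample_id!r} has no tissue patches")
    if a.min() < 0 or a.max() >= k:
        raise ValueError("assignment index outside [0, k)")
    tallies = np.bincount(a, minlength=k).astype(float)
    return CompositionVector(sample_id, tallies / a.size, int(a.size))


def impact_scores(assignments_by_patient: Sequence[np.ndarray],
                  bcr_labels: Sequence[int], k: int,
                  smoothing: float = 1.0) -> np.ndarray:
    """Per-cluster impact: smoothed fraction of patches from positive patients.

    ``impact_c = (n_c+ + s) / (n_c+ + n_c- + 2 s)`` where ``n_c+/-`` count
    patches in cluster c contributed by outcome-positive/negative patients.
    0.5 is neutral; with ``smoothing > 0`` scores are strictly inside (0, 1).
    """
    y = np.asarray(bcr_labels, dtype=int)
    if len(assignments_by_patient) != len(y):
        raise ValueError("one assignment array per patient label required")
    if len(np.unique(y)) < 2:
        raise ValueError("impact scores require both outcome classes")
    pos = np.zeros(k)
    neg = np.zeros(k)
    for a, lab in zip(assignments_by_patient, y):
        a = np.asarray(a, dtype=int)
        if a.size and (a.min() < 0 or a.max() >= k):
            raise ValueError("assignment index outside [0, k)")
        counts = np.bincount(a, minlength=k)
        if lab == 1:
            pos += counts
        else:
            neg += counts
    denom = pos + neg + 2 * smoothing
    if smoothing == 0 and np.any(denom == 0):
        raise ValueError("empty cluster with zero smoothing")
    return (pos + smoothing) / denom


def display_size(impact) -> np.ndarray | float:
    """Rendered size of a feature: ``|0.5 - impact| + 2.5``."""
    arr = np.asarray(impact, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("impact scores must lie in [0, 1]")
    out = np.abs(0.5 - arr) + 2.5
    return float(out) if out.ndim == 0 else out


def representative_patches(codebook: Codebook, embeddings: np.ndarray,
                           patch_refs: Sequence, n: int = 3) -> dict[int, list]:
    """Per cluster, the ``n`` assigned patches closest to its centroid.

    Returns ``{cluster: [(ref, distance), ...]}`` sorted by ascending
    distance with ties broken by original patch order; clusters with no
    assigned patch map to an empty list.  Clusters with fewer than ``n``
    patches return what they have.
    """
    X = np.asarray(embeddings, dtype=float)
    labels = assign(codebook, X)
    out: dict[int, list] = {c: [] for c in range(codebook.k)}
    for c in range(codebook.k):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        dist = np.linalg.norm(X[idx] - codebook.centroids[c], axis=1)
        order = np.argsort(dist, kind="stable")[:n]
        out[c] = [(patch_refs[idx[j]], float(dist[j])) for j in order]
    return out


def feature_map(patchset: PatchSet, assignments: np.ndarray,
                codebook: Codebook) -> tuple[np.ndarray, np.ndarray]:
    """Impact-score grid aligned to the tiling lattice.

    Returns ``(values, high)``: per-cell impact of the assigned cluster
    (NaN on background) and a boolean flag for impact > 0.5 (the red/blue
    split of the rendered map).  ``assignments`` covers the tissue patches
    of ``patchset`` in order.
    """
    if codebook.impact is None:
        raise ValueError("codebook carries no impact scores")
    if patchset.tissue is None:
        raise ValueError("patchset has no tissue flags")
    if (patchset.origins % patchset.stride).any():
        raise ValueError("patch origins are off the stride lattice")
    a = np.asarray(assignments, dtype=int)
    tissue_idx = np.flatnonzero(patchset.tissue)
    if a.shape[0] != tissue_idx.size:
        raise ValueError("one assignment per tissue patch required")
    cells = patchset.origins // patchset.stride
    n_cols = int(cells[:, 0].max()) + 1 if len(cells) else 0
    n_rows = int(cells[:, 1].max()) + 1 if len(cells) else 0
    values = np.full((n_rows, n_cols), np.nan)
    high = np.zeros((n_rows, n_cols), dtype=bool)
    for a_i, p_i in zip(a, tissue_idx):
        cx, cy = cells[p_i]
        values[cy, cx] = codebook.impact[a_i]
        high[cy, cx] = codebook.impact[a_i] > 0.5
    return values, high
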