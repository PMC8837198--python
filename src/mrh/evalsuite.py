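"""Evaluation battery for translated volumes.

Covers the metrics used to judge virtual-stain predictions against a
reference: RMSE, voxel-wise R^2 (squared Pearson correlation), SSIM,
ROC/AUC against an Otsu-binarized reference (with explicit polarity
for hypo- vs hyper-intense targets), a t-SNE embedding of patch
predictions or features, and per-group channel signal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity
from sklearn.manifold import TSNE
from sklearn.metrics import roc_curve, auc as _auc

from .patches import PatchSet

__all__ = [
    "RocResult",
    "rmse",
    "voxelwise_r2",
    "ssim",
    "otsu_threshold",
    "roc_analysis",
    "tsne_embed",
    "signal_profiles",
]


def _masked_pair(pred, ref, mask):
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    mask = np.asarray(mask, bool)
    if pred.shape != ref.shape or pred.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, ref {ref.shape}, mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty mask")
    return pred[mask], ref[mask]


def rmse(pred: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square error over within-mask voxels (symmetric)."""
    p, r = _masked_pair(pred, ref, mask)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def voxelwise_r2(pred: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> float:
    """Squared Pearson correlation of within-mask voxel pairs.

    Note this is symmetric and sign-blind: ``pred = -ref`` also gives
    R^2 = 1, so inspect the sign of the correlation separately when
    polarity matters.
    """
    p, r = _masked_pair(pred, ref, mask)
    if np.ptp(r) == 0:
        raise ValueError("reference is constant within mask: R^2 undefined")
    if np.ptp(p) == 0:
        return 0.0
    return float(np.corrcoef(p, r)[0, 1] ** 2)


def ssim(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray,
    window: int = 7,
    dynamic_range: float | None = None,
) -> float:
    """Structural similarity, Gaussian-windowed, averaged within the mask.

    ``dynamic_range`` defaults to the within-mask reference value range.
    """
    p, r = _masked_pair(pred, ref, mask)     # validation only
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if window > min(pred.shape):
        raise ValueError(
            f"window {window} exceeds the smallest volume dimension "
            f"{min(pred.shape)}"
        )
    if dynamic_range is None:
        dynamic_range = float(np.ptp(r))
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be > 0")
    _, smap = structural_similarity(
        ref,
        pred,
        win_size=window,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=dynamic_range,
        full=True,
    )
    return float(smap[np.asarray(mask, bool)].mean())


def otsu_threshold(ref: np.ndarray, mask: np.ndarray) -> float:
    """Otsu's between-class-variance-maximizing threshold within the mask."""
    vals = np.asarray(ref, float)[np.asarray(mask, bool)]
    if np.ptp(vals) == 0:
        raise ValueError("reference is constant within mask")
    return float(threshold_otsu(vals))


@dataclass
class RocResult:
    """ROC sweep of a continuous prediction against a binarized reference."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    reference_threshold: float
    threshold_method: str
    polarity: str                     # 'hypo' or 'hyper'


def roc_analysis(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray,
    polarity: str = "hypo",
    pred_polarity: str | None = None,
) -> RocResult:
    """ROC of the prediction for detecting the reference's extreme class.

    The reference is binarized at its Otsu threshold; with polarity
    ``'hypo'`` the positive class is *below* the threshold (e.g.
    myelinated tracts in an auto-fluorescence-like stain), with
    ``'hyper'`` the converse.  ``pred_polarity`` states how the
    *prediction* encodes the positive class and defaults to the
    reference polarity; pass the opposite value for a
    contrast-inverted prediction.  AUC is computed by the trapezoidal
    rule over the swept prediction values.
    """
    if polarity not in ("hypo", "hyper"):
        raise ValueError("polarity must be 'hypo' or 'hyper'")
    pred_polarity = polarity if pred_polarity is None else pred_polarity
    if pred_polarity not in ("hypo", "hyper"):
        raise ValueError("pred_polarity must be 'hypo' or 'hyper'")
    p, r = _masked_pair(pred, ref, mask)
    thr = otsu_threshold(ref, mask)
    labels = r < thr if polarity == "hypo" else r > thr
    if labels.all() or not labels.any():
        raise ValueError("reference binarization produced a single class")
    scores = -p if pred_polarity == "hypo" else p
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_auc(fpr, tpr)),
        reference_threshold=thr,
        threshold_method="otsu",
        polarity=polarity,
    )


def tsne_embed(
    vectors: np.ndarray | PatchSet,
    n: int | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """2D t-SNE embedding of per-patch vectors.

    ``vectors`` may be an ``(m, d)`` array (e.g. flattened predicted
    patches or intermediate-layer features) or a PatchSet, in which
    case its flattened target patches are used.  ``n`` points are
    subsampled deterministically under ``seed``; carried-through
    ``labels`` (e.g. hypo/hyper/surface classes) are returned aligned
    with the embedding for plotting.
    """
    if isinstance(vectors, PatchSet):
        vectors = vectors.targets.reshape(vectors.n, -1)
    vectors = np.asarray(vectors, float)
    m = vectors.shape[0]
    n = m if n is None else n
    if n > m:
        raise ValueError(f"requested {n} patches but only {m} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n, replace=False) if n < m else np.arange(m)
    sel = vectors[idx]
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(sel)
    out_labels = None if labels is None else np.asarray(labels)[idx]
    return emb, out_labels


def signal_profiles(
    patchset: PatchSet, group_labels: np.ndarray
) -> pd.DataFrame:
    """Per-group mean +/- sd center-voxel signal profile across channels.

    Groups with no members are omitted with a warning.  Channel order
    follows the patch set's channel manifest (so direction- or
    frequency-ordered groups read left to right).
    """
    import warnings

    group_labels = np.asarray(group_labels)
    if group_labels.shape[0] != patchset.n:
        raise ValueError("every patch needs a group label")
    centers = patchset.center_inputs()             # (n, C)
    C = patchset.n_channels
    ch_labels = patchset.channel_labels or [f"ch{i:02d}" for i in range(C)]
    rows = []
    for g in pd.unique(group_labels):
        sel = centers[group_labels == g]
        if sel.shape[0] == 0:
            warnings.warn(f"group {g!r} is empty; omitted", stacklevel=2)
            continue
        for c in range(C):
            rows.append(
                {
                    "group": g,
                    "channel": c,
                    "label": ch_labels[c],
                    "mean": float(sel[:, c].mean()),
                    "sd": float(sel[:, c].std()),
                    "n": int(sel.shape[0]),
                }
            )
    return pd.DataFrame(rows)
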