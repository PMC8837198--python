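"""Paired input/target patch datasets for patch-based translation.

Patches are 2D in-plane windows (default 3x3) with all channels
stacked, taken in the slice plane perpendicular to a chosen axis.
Sampling masks constrain only the *center* voxel, so brain-surface
patches whose outer ring leaves the mask are kept — those patches are
an informative tissue class of their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import MultiContrastVolume, TargetVolume, check_same_grid

__all__ = [
    "PatchSet",
    "NormalizationStats",
    "extract_patches",
    "replicate_center",
    "split_validation",
    "normalize_channels",
    "reassemble_k1",
]


@dataclass
class NormalizationStats:
    """Per-channel location/scale computed on training data within mask."""

    location: np.ndarray
    scale: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        self.scale = np.asarray(self.scale, float)
        if self.location.shape != self.scale.shape:
            raise ValueError("location/scale shape mismatch")
        bad = np.flatnonzero(self.scale <= 0)
        if bad.size:
            names = (
                [self.channel_labels[i] for i in bad]
                if self.channel_labels
                else bad.tolist()
            )
            raise ValueError(f"non-positive scale for channel(s) {names}")

    @property
    def n_channels(self) -> int:
        return self.location.size

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Normalize an array whose last axis is channels."""
        if x.shape[-1] != self.n_channels:
            raise ValueError(
                f"stats for {self.n_channels} channels, data has {x.shape[-1]}"
            )
        return (x - self.location) / self.scale

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.location


@dataclass
class ScalarStats:
    """Location/scale for the (single-channel) target intensity."""

    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("non-positive target scale")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.location) / self.scale

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.location


@dataclass
class PatchSet:
    """Aligned input/target patches with their provenance.

    ``inputs``: ``(n, k, k, C)``; ``targets``: ``(n, k, k)``;
    ``coords``: ``(n, 3)`` center-voxel indices; ``axis``: slice axis.
    """

    inputs: np.ndarray
    targets: np.ndarray
    coords: np.ndarray
    axis: int = 0
    subject_ids: np.ndarray | None = None
    channel_labels: list[str] | None = None
    norm_stats: NormalizationStats | None = None
    target_stats: ScalarStats | None = None

    def __post_init__(self) -> None:
        if self.inputs.ndim != 4 or self.targets.ndim != 3:
            raise ValueError("inputs must be (n,k,k,C), targets (n,k,k)")
        n, k = self.inputs.shape[:2]
        if k % 2 == 0:
            raise ValueError(f"patch size k={k} must be odd")
        if self.targets.shape != (n, k, k):
            raise ValueError("inputs/targets misaligned")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if self.subject_ids is None:
            self.subject_ids = np.zeros(n, dtype=int)

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    @property
    def k(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[3]

    def center_inputs(self) -> np.ndarray:
        """Center-voxel channel vectors, ``(n, C)``."""
        c = self.k // 2
        return self.inputs[:, c, c, :]

    def center_targets(self) -> np.ndarray:
        c = self.k // 2
        return self.targets[:, c, c]

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return replace(
            self,
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            coords=self.coords[idx],
            subject_ids=self.subject_ids[idx],
        )

    def select_channels(self, channels: np.ndarray) -> "PatchSet":
        channels = np.asarray(channels, int)
        labels = (
            [self.channel_labels[i] for i in channels]
            if self.channel_labels
            else None
        )
        stats = None
        if self.norm_stats is not None:
            stats = NormalizationStats(
                self.norm_stats.location[channels],
                self.norm_stats.scale[channels],
                labels,
            )
        return replace(
            self,
            inputs=self.inputs[..., channels],
            channel_labels=labels,
            norm_stats=stats,
        )


def _padded(data: np.ndarray, pad: int, axis: int) -> np.ndarray:
    """Edge-replicate padding of the two in-plane axes only."""
    widths = [(0, 0)] * data.ndim
    for a in range(3):
        if a != axis:
            widths[a] = (pad, pad)
    return np.pad(data, widths, mode="edge")


def _window(center: np.ndarray, half: int, axis: int) -> tuple:
    sl = []
    for a in range(3):
        if a == axis:
            sl.append(center[a])
        else:
            sl.append(slice(center[a], center[a] + 2 * half + 1))
    return tuple(sl)


def extract_patches(
    volume: MultiContrastVolume,
    target: TargetVolume,
    mask: np.ndarray,
    k: int = 3,
    n: int = 1000,
    axis: int = 0,
    region_mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: int = 0,
) -> PatchSet:
    """Sample ``n`` paired k x k patches with centers inside the mask.

    Centers are drawn uniformly *without replacement* from
    ``mask & region_mask``.  Patches are in-plane (perpendicular to
    ``axis``); windows reaching past the volume edge read
    edge-replicated values, and voxels outside the mask are retained
    as-is — the mask constrains only the center.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    check_same_grid(volume.data, target.data, mask)
    eligible = np.asarray(mask, bool)
    if region_mask is not None:
        eligible = eligible & np.asarray(region_mask, bool)
    centers = np.argwhere(eligible)
    if n > centers.shape[0]:
        raise ValueError(
            f"requested {n} patches but only {centers.shape[0]} eligible centers"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pick = rng.choice(centers.shape[0], size=n, replace=False)
    centers = centers[pick]

    half = k // 2
    vpad = _padded(volume.data, half, axis)
    tpad = _padded(target.data, half, axis)
    C = volume.n_channels
    inputs = np.empty((n, k, k, C), dtype=volume.data.dtype)
    targets = np.empty((n, k, k), dtype=target.data.dtype)
    for i, c in enumerate(centers):
        # centers are already offset by `half` in padded in-plane axes
        inputs[i] = vpad[_window(np.asarray(c), half, axis)]
        targets[i] = tpad[_window(np.asarray(c), half, axis)]
    return PatchSet(
        inputs=inputs,
        targets=targets,
        coords=centers,
        axis=axis,
        subject_ids=np.full(n, subject_id),
        channel_labels=list(volume.channel_labels),
    )


def replicate_center(patchset: PatchSet) -> PatchSet:
    """Assign every voxel of each input patch the center voxel's signals.

    Probes whether a model relies on within-patch spatial pattern or on
    the multi-contrast signal vector alone; targets are unchanged.
    Idempotent.
    """
    c = patchset.k // 2
    center = patchset.inputs[:, c : c + 1, c : c + 1, :]
    inputs = np.broadcast_to(center, patchset.inputs.shape).copy()
    return replace(patchset, inputs=inputs)


def split_validation(
    patchset: PatchSet, n_val: int = 1000, seed: int = 0
) -> tuple[PatchSet, PatchSet]:
    """Randomly hold out ``n_val`` patches as a validation set.

    The split is a partition: disjoint and exhaustive.  ``n_val = 0``
    is allowed (with a warning) and disables early stopping downstream.
    """
    if n_val >= patchset.n:
        raise ValueError(f"n_val={n_val} must be < n={patchset.n}")
    if n_val == 0:
        warnings.warn(
            "empty validation set: early stopping will be disabled",
            stacklevel=2,
        )
        return patchset, patchset.subset(np.array([], dtype=int))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patchset.n)
    return patchset.subset(np.sort(perm[n_val:])), patchset.subset(np.sort(perm[:n_val]))


def normalize_channels(
    data: PatchSet | MultiContrastVolume,
    stats: NormalizationStats | str = "fit",
    mask: np.ndarray | None = None,
    normalize_target: bool = False,
) -> tuple[PatchSet | MultiContrastVolume, NormalizationStats]:
    """Per-channel z-scoring: ``(x - location) / scale``.

    With ``stats="fit"`` the statistics are computed from the given
    data (within ``mask`` for a volume; over all patch voxels for a
    PatchSet) — fit only on training data and reuse the returned stats
    elsewhere.  For a PatchSet, ``normalize_target=True`` additionally
    z-scores the target intensities and stores the inverse transform.
    """
    if isinstance(data, MultiContrastVolume):
        x = data.data
        if stats == "fit":
            sel = x[np.asarray(mask, bool)] if mask is not None else x.reshape(-1, x.shape[-1])
            stats = NormalizationStats(
                sel.mean(axis=0), sel.std(axis=0), list(data.channel_labels)
            )
        return data.with_data(stats.apply(x).astype(x.dtype)), stats

    ps: PatchSet = data
    if stats == "fit":
        flat = ps.inputs.reshape(-1, ps.n_channels)
        stats = NormalizationStats(
            flat.mean(axis=0), flat.std(axis=0), ps.channel_labels
        )
    inputs = stats.apply(ps.inputs.astype(float))
    targets = ps.targets
    tstats = ps.target_stats
    if normalize_target:
        if tstats is None:
            tstats = ScalarStats(float(targets.mean()), float(targets.std()))
        targets = tstats.apply(targets.astype(float))
    return (
        replace(ps, inputs=inputs, targets=targets,
                norm_stats=stats, target_stats=tstats),
        stats,
    )


def reassemble_k1(patchset: PatchSet, shape: tuple[int, int, int]) -> np.ndarray:
    """Scatter k=1 target patches back onto a volume grid (round-trip check)."""
    if patchset.k != 1:
        raise ValueError("reassembly is defined for k=1 patch sets")
    out = np.zeros(shape, dtype=patchset.targets.dtype)
    c = patchset.coords
    out[c[:, 0], c[:, 1], c[:, 2]] = patchset.targets[:, 0, 0]
    return out
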