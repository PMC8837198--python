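"""Synthetic tissue phantoms with a known signal-to-stain ground truth.

The phantom stands in for co-registered multi-contrast MRI and histology
volumes.  It emulates the features that matter for patch-based
translation networks and their analysis:

* a multi-class tissue label geometry (smooth "blobs" inside an
  ellipsoidal brain mask, plus background),
* per-class, per-channel mean signal levels with an optional
  direction-to-direction oscillation across a designated channel group
  (mimicking how diffusion-weighted signal varies across encoding
  directions, more strongly in some tissue classes than others),
* a smooth per-channel spatial modulation field, so that signals vary
  within a class and linear/quadratic mappings are identifiable from
  voxel data,
* Rician noise on the input channels (magnitude-MRI noise model),
* a known deterministic mapping from noise-free channel signals to the
  target stain intensity, and
* random in-plane displacement fields whose magnitudes follow a Chi
  distribution with 2 degrees of freedom, to simulate residual
  registration mismatch between inputs and targets.

The target volume is always computed from the *noise-free* signals, so
the ground truth is exact and recovery metrics are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import MultiContrastVolume, TargetVolume, check_same_grid

__all__ = [
    "GroundTruthMapping",
    "TissuePhantomSpec",
    "DisplacementField",
    "make_phantom",
    "add_rician_noise",
    "make_displacement_field",
    "warp_volume",
    "chi2_scale_for_mean",
    "default_phantom_spec",
]


# --------------------------------------------------------------------------
# Ground-truth mapping
# --------------------------------------------------------------------------

@dataclass
class GroundTruthMapping:
    """Deterministic mapping from channel signals to stain intensity.

    Forms
    -----
    ``linear``
        ``y = intercept + w . s`` with one weight per channel.
    ``quadratic``
        linear plus per-channel square terms and optional pairwise
        products.
    ``subset-dependent``
        a quadratic (with cross terms) restricted to ``active_channels``;
        the target genuinely depends on that subset only.
    ``lookup-by-class``
        per-class intensities indexed by the tissue label (ignores the
        signals entirely).
    """

    form: str
    weights: np.ndarray | None = None          # (C,) linear weights
    intercept: float = 0.0
    quad_weights: np.ndarray | None = None     # (C,) weights on s_i**2
    cross_terms: list = field(default_factory=list)  # [(i, j, w), ...]
    class_intensities: np.ndarray | None = None      # (n_classes,) for lookup
    active_channels: np.ndarray | None = None

    _FORMS = ("linear", "quadratic", "subset-dependent", "lookup-by-class")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown mapping form {self.form!r}")
        if self.form == "lookup-by-class":
            if self.class_intensities is None:
                raise ValueError("lookup-by-class requires class_intensities")
            self.class_intensities = np.asarray(self.class_intensities, float)
            if self.active_channels is None:
                self.active_channels = np.array([], dtype=int)
            return
        if self.weights is None:
            raise ValueError(f"{self.form} mapping requires weights")
        self.weights = np.asarray(self.weights, float)
        if self.quad_weights is not None:
            self.quad_weights = np.asarray(self.quad_weights, float)
        if self.active_channels is None:
            active = set(np.flatnonzero(self.weights).tolist())
            if self.quad_weights is not None:
                active |= set(np.flatnonzero(self.quad_weights).tolist())
            for i, j, w in self.cross_terms:
                if w != 0:
                    active |= {i, j}
            self.active_channels = np.array(sorted(active), dtype=int)
        else:
            self.active_channels = np.asarray(self.active_channels, dtype=int)

    @property
    def n_channels(self) -> int | None:
        return None if self.weights is None else self.weights.size

    def apply(self, signals: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the mapping on signals of shape ``(..., C)``."""
        if self.form == "lookup-by-class":
            if labels is None:
                raise ValueError("lookup-by-class mapping needs a label volume")
            out = np.zeros(labels.shape, float)
            fg = labels > 0
            out[fg] = self.class_intensities[labels[fg] - 1]
            return out
        signals = np.asarray(signals, float)
        y = self.intercept + signals @ self.weights
        if self.quad_weights is not None:
            y = y + (signals ** 2) @ self.quad_weights
        for i, j, w in self.cross_terms:
            y = y + w * signals[..., i] * signals[..., j]
        return y


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

@dataclass
class TissuePhantomSpec:
    """Full description of a synthetic phantom.

    Parameters
    ----------
    shape
        3D grid dimensions in voxels.
    n_classes
        Number of foreground tissue classes (label 0 is background).
    channel_means
        ``(n_classes, C)`` mean signal per class and channel, arbitrary
        units, nonnegative.
    osc_amplitude
        ``(n_classes,)`` oscillation amplitude per class, applied across
        ``osc_channels`` (the DWI-like channel group).
    osc_channels
        Channel indices forming the direction-ordered group over which
        the sinusoidal signal oscillation runs.
    osc_period
        Number of consecutive channels per oscillation cycle.
    noise_sigma_fraction
        Rician noise sigma as a fraction of the within-mask mean
        absolute signal of each channel.
    spatial_modulation
        Relative amplitude of the smooth, noise-free per-channel
        multiplicative modulation field (0 gives piecewise-constant
        signals per class).
    geometry_smoothness
        Gaussian smoothing sigma (voxels) of the random field whose
        quantiles delineate the tissue classes; larger values give
        larger blobs.
    """

    shape: tuple[int, int, int]
    n_classes: int
    channel_means: np.ndarray
    mapping: GroundTruthMapping
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    osc_amplitude: np.ndarray | None = None
    osc_channels: np.ndarray | None = None
    osc_period: int = 6
    noise_sigma_fraction: float = 0.0
    spatial_modulation: float = 0.15
    geometry_smoothness: float = 4.0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 tissue classes plus background")
        self.channel_means = np.atleast_2d(np.asarray(self.channel_means, float))
        if self.channel_means.shape[0] != self.n_classes:
            raise ValueError(
                f"channel_means has {self.channel_means.shape[0]} rows for "
                f"{self.n_classes} classes"
            )
        if np.any(self.channel_means < 0):
            raise ValueError("channel means must be nonnegative")
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise_sigma_fraction must be >= 0")
        C = self.n_channels
        if self.osc_amplitude is None:
            self.osc_amplitude = np.zeros(self.n_classes)
        self.osc_amplitude = np.asarray(self.osc_amplitude, float)
        if self.osc_channels is None:
            self.osc_channels = np.array([], dtype=int)
        self.osc_channels = np.asarray(self.osc_channels, dtype=int)
        if self.osc_channels.size and self.osc_channels.max() >= C:
            raise ValueError("osc_channels out of range")
        if self.mapping.n_channels is not None and self.mapping.n_channels != C:
            raise ValueError(
                f"mapping has {self.mapping.n_channels} channels, spec has {C}"
            )
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:02d}" for i in range(C)]
        if len(self.channel_labels) != C:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.channel_means.shape[1]

    def class_signals(self) -> np.ndarray:
        """Per-class, per-channel noise-free signal including oscillation.

        Returns ``(n_classes, C)``.  The oscillation is a sinusoid along
        the position within the designated channel group, with a fixed
        per-class phase, clipped at zero.
        """
        sig = self.channel_means.copy()
        if self.osc_channels.size:
            pos = np.arange(self.osc_channels.size)
            for c in range(self.n_classes):
                phase = 2.0 * np.pi * c / max(self.n_classes, 1)
                osc = self.osc_amplitude[c] * np.sin(
                    2.0 * np.pi * pos / self.osc_period + phase
                )
                sig[c, self.osc_channels] += osc
        return np.clip(sig, 0.0, None)


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def _label_volume(spec: TissuePhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth-random-field quantile labels: 0 background, 1..n_classes."""
    mask = _ellipsoid_mask(spec.shape)
    fieldv = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), spec.geometry_smoothness
    )
    labels = np.zeros(spec.shape, dtype=np.int16)
    vals = fieldv[mask]
    # equal-volume classes by quantile thresholds of the smoothed field
    qs = np.quantile(vals, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
    labels[mask] = 1 + np.searchsorted(qs, vals)
    for c in range(1, spec.n_classes + 1):
        if not np.any(labels == c):
            warnings.warn(f"tissue class {c} has zero voxels", stacklevel=2)
    return labels


def _modulation_fields(
    spec: TissuePhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative fields, one per channel, mean ~1."""
    C = spec.n_channels
    if spec.spatial_modulation == 0:
        return np.ones(spec.shape + (C,))
    out = np.empty(spec.shape + (C,))
    sigma = max(min(spec.shape) / 6.0, 2.0)
    for c in range(C):
        f = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma)
        f = f / max(np.abs(f).max(), 1e-12)      # into [-1, 1]
        out[..., c] = 1.0 + spec.spatial_modulation * f
    return out


def add_rician_noise(
    volume: np.ndarray,
    sigma_fraction: float,
    mask: np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Corrupt a scalar volume with Rician noise.

    Each voxel value ``v`` becomes ``sqrt((v + n1)^2 + n2^2)`` with
    ``n1, n2 ~ Normal(0, sigma)`` and
    ``sigma = sigma_fraction * mean(|volume| within mask)``.
    """
    if sigma_fraction < 0:
        raise ValueError("sigma_fraction must be >= 0")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask: Rician sigma reference level undefined")
    volume = np.asarray(volume, float)
    if sigma_fraction == 0:
        return volume.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = sigma_fraction * float(np.mean(np.abs(volume[mask])))
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + n1) ** 2 + n2 ** 2)


def make_phantom(
    spec: TissuePhantomSpec, seed: int
) -> tuple[MultiContrastVolume, TargetVolume, np.ndarray, np.ndarray]:
    """Generate a phantom: inputs, target, brain mask, label volume.

    The input channels carry class signal + oscillation, the smooth
    spatial modulation, and Rician noise.  The target is the mapping
    applied to the noise-free signals, so it is exact ground truth.
    """
    rng = np.random.default_rng(seed)
    labels = _label_volume(spec, rng)
    mask = labels > 0
    class_sig = spec.class_signals()                   # (n_classes, C)
    C = spec.n_channels

    clean = np.zeros(spec.shape + (C,))
    fg = labels > 0
    clean[fg] = class_sig[labels[fg] - 1]
    clean *= _modulation_fields(spec, rng)

    target = spec.mapping.apply(clean, labels)
    target[~mask] = 0.0

    noisy = np.empty_like(clean)
    for c in range(C):
        noisy[..., c] = add_rician_noise(
            clean[..., c], spec.noise_sigma_fraction, mask, rng
        ) if spec.noise_sigma_fraction > 0 else clean[..., c]

    vol = MultiContrastVolume(noisy, list(spec.channel_labels), spec.voxel_size)
    tgt = TargetVolume(target, "ground_truth", spec.voxel_size)
    return vol, tgt, mask, labels


def make_clean_phantom(
    spec: TissuePhantomSpec, seed: int
) -> tuple[MultiContrastVolume, TargetVolume, np.ndarray, np.ndarray]:
    """Same geometry/signals as :func:`make_phantom` but without noise."""
    noisy_frac = spec.noise_sigma_fraction
    spec.noise_sigma_fraction = 0.0
    try:
        return make_phantom(spec, seed)
    finally:
        spec.noise_sigma_fraction = noisy_frac


# --------------------------------------------------------------------------
# Displacement mismatch simulation
# --------------------------------------------------------------------------

def chi2_scale_for_mean(mean_displacement: float) -> float:
    """Chi(2) scale sigma such that the mean magnitude equals the given value.

    For independent x/y components ~ Normal(0, sigma^2) the magnitude is
    Chi with 2 degrees of freedom (Rayleigh) with mean ``sigma*sqrt(pi/2)``.
    """
    return mean_displacement / np.sqrt(np.pi / 2.0)


@dataclass
class DisplacementField:
    """In-plane per-voxel displacement, in voxel units.

    ``field`` has shape ``(x, y, z, 2)`` holding the two in-plane
    components for the plane perpendicular to ``axis``.  Through-plane
    displacement is zero.
    """

    field: np.ndarray
    axis: int = 0
    grid_spacing_mm: float = 1.0
    magnitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.field.ndim != 4 or self.field.shape[3] != 2:
            raise ValueError("field must have shape (x, y, z, 2)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.field.shape[:3]

    def magnitudes(self) -> np.ndarray:
        return np.sqrt((self.field ** 2).sum(axis=3))


def make_displacement_field(
    shape: tuple[int, int, int],
    grid_spacing_mm: float,
    voxel_size_mm: float,
    magnitude_scale_voxels: float,
    seed: int,
    axis: int = 0,
) -> DisplacementField:
    """Random smooth in-plane displacement field.

    Independent Gaussian x/y components (sigma = ``magnitude_scale_voxels``)
    are drawn on a coarse in-plane control grid for every slice along
    ``axis`` and propagated to all voxels by cubic B-spline
    interpolation.  Coarse-node magnitudes are therefore Chi-distributed
    with 2 degrees of freedom; each slice gets an independent field.
    """
    if grid_spacing_mm <= voxel_size_mm:
        raise ValueError("grid spacing must exceed the voxel size")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    inplane = [a for a in range(3) if a != axis]
    h, w = shape[inplane[0]], shape[inplane[1]]
    step = grid_spacing_mm / voxel_size_mm          # coarse spacing in voxels
    nh = max(int(np.ceil(h / step)) + 1, 2)
    nw = max(int(np.ceil(w / step)) + 1, 2)

    field = np.zeros(shape + (2,))
    if magnitude_scale_voxels == 0:
        return DisplacementField(field, axis, grid_spacing_mm, magnitude_scale_voxels)

    ii, jj = np.meshgrid(np.arange(h) / step, np.arange(w) / step, indexing="ij")
    coords = np.stack([ii, jj])
    for s in range(shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = s
        for comp in range(2):
            coarse = rng.normal(0.0, magnitude_scale_voxels, (nh, nw))
            fine = ndimage.map_coordinates(coarse, coords, order=3, mode="nearest")
            field[tuple(sl) + (comp,)] = fine
    return DisplacementField(field, axis, grid_spacing_mm, magnitude_scale_voxels)


def coarse_grid_magnitudes(
    shape: tuple[int, int, int],
    grid_spacing_mm: float,
    voxel_size_mm: float,
    magnitude_scale_voxels: float,
    seed: int,
    n_nodes: int | None = None,
) -> np.ndarray:
    """Magnitudes of coarse-grid control displacements (Chi(2) samples).

    Useful for checking the configured mismatch level; uses the same
    component distribution as :func:`make_displacement_field`.
    """
    rng = np.random.default_rng(seed)
    if n_nodes is None:
        inplane = np.prod([s for a, s in enumerate(shape) if a != 0])
        step = grid_spacing_mm / voxel_size_mm
        n_nodes = int(inplane / step ** 2) * shape[0]
    comp = rng.normal(0.0, magnitude_scale_voxels, (int(n_nodes), 2))
    return np.sqrt((comp ** 2).sum(axis=1))


def warp_volume(
    volume: np.ndarray,
    field: DisplacementField,
    interpolation: str = "linear",
) -> np.ndarray:
    """Pull-back resample a scalar volume through a displacement field.

    ``out(x) = volume(x + d(x))``; reads falling outside the volume are
    clamped to the edge.
    """
    volume = np.asarray(volume)
    check_same_grid(volume, field.field)
    order = {"nearest": 0, "linear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    inplane = [a for a in range(3) if a != field.axis]
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in volume.shape],
                         indexing="ij")
    coords = [c.copy() for c in coords]
    coords[inplane[0]] += field.field[..., 0]
    coords[inplane[1]] += field.field[..., 1]
    return ndimage.map_coordinates(
        volume.astype(float), coords, order=order, mode="nearest"
    )


# --------------------------------------------------------------------------
# Convenience factory
# --------------------------------------------------------------------------

def default_phantom_spec(
    shape: tuple[int, int, int] = (48, 48, 48),
    n_channels: int = 12,
    n_classes: int = 4,
    mapping_form: str = "subset-dependent",
    active_channels: tuple[int, ...] = (0, 1, 2),
    noise_sigma_fraction: float = 0.05,
    spatial_modulation: float = 0.15,
    uninformative_decoys: bool = False,
    geometry_smoothness: float = 4.0,
    seed: int = 0,
) -> TissuePhantomSpec:
    """A ready-to-use phantom spec with plausible signal levels.

    Channel means are drawn once (deterministically from ``seed``) in
    [0.4, 1.6]; the last two thirds of the channels form the DWI-like
    oscillation group, with class-dependent amplitude so that some
    classes show visibly larger direction-to-direction variation.
    Mapping coefficients are scaled so target intensities are O(1).

    With ``uninformative_decoys``, channels outside ``active_channels``
    get class-independent means and no oscillation: they then carry no
    information about the target at all.  Without it, decoy channels
    still encode the tissue class, so their signals are *redundant*
    with the active channels — a translation network can lean on them,
    and the perturbation analysis will honestly report such shared
    contributions.  Channel-importance recovery experiments therefore
    use uninformative decoys; realism experiments use the default.
    """
    rng = np.random.default_rng(seed)
    C = n_channels
    means = rng.uniform(0.4, 1.6, size=(n_classes, C))
    osc_channels = np.arange(C // 3, C)
    osc_amp = rng.uniform(0.0, 0.35, size=n_classes)
    if uninformative_decoys and mapping_form != "lookup-by-class":
        decoys = np.setdiff1d(np.arange(C), np.asarray(active_channels, int))
        means[:, decoys] = means[0, decoys]          # class-independent
        osc_channels = np.setdiff1d(osc_channels, decoys)

    active = np.asarray(active_channels, dtype=int)
    w = np.zeros(C)
    q = np.zeros(C)
    cross: list = []
    if mapping_form == "lookup-by-class":
        mapping = GroundTruthMapping(
            "lookup-by-class",
            class_intensities=np.linspace(0.2, 0.9, n_classes),
        )
    else:
        w[active] = rng.uniform(0.4, 1.0, active.size) * rng.choice([-1, 1], active.size)
        if mapping_form in ("quadratic", "subset-dependent"):
            q[active] = rng.uniform(0.2, 0.6, active.size)
            if active.size >= 2:
                cross = [(int(active[0]), int(active[1]), 0.5)]
        if mapping_form == "quadratic":
            # quadratic over all channels, not subset-restricted
            w = rng.uniform(-0.5, 0.5, C)
            q = rng.uniform(0.0, 0.3, C)
            active = np.arange(C)
        mapping = GroundTruthMapping(
            mapping_form if mapping_form != "quadratic" else "quadratic",
            weights=w,
            intercept=0.5,
            quad_weights=q if np.any(q) else None,
            cross_terms=cross,
            active_channels=active,
        )
    return TissuePhantomSpec(
        shape=shape,
        n_classes=n_classes,
        channel_means=means,
        mapping=mapping,
        osc_amplitude=osc_amp,
        osc_channels=osc_channels,
        noise_sigma_fraction=noise_sigma_fraction,
        spatial_modulation=spatial_modulation,
        geometry_smoothness=geometry_smoothness,
    )
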