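"""Derived MR parameter maps and polynomial fitting baselines.

Implements the conventional quantitative maps that multi-contrast
acquisitions support — magnetization transfer ratio (MTR), diffusion
tensor metrics (MD, FA, radial diffusivity) via the log-linear fit, and
two-shell diffusion kurtosis (MD, MK) — plus the first/second-order
polynomial regression baselines that patch-translation networks are
compared against.

Units follow convention: b-values in s/mm^2, diffusivities in mm^2/s,
MTR and FA dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionScheme",
    "ParameterMaps",
    "compute_mtr",
    "fit_tensor_loglinear",
    "fit_dki_loglinear",
    "PolynomialBaseline",
    "polynomial_baseline_fit",
    "polynomial_baseline_predict",
]


# --------------------------------------------------------------------------
# Diffusion scheme
# --------------------------------------------------------------------------

@dataclass
class DiffusionScheme:
    """Acquisition scheme: one b-value and unit direction per image.

    ``b_values`` in s/mm^2; ``directions`` is ``(n, 3)`` with unit rows
    for b > 0 (b = 0 rows may be zero).  ``oscillation_hz`` optionally
    records an OGSE-like oscillation frequency per image.
    """

    b_values: np.ndarray
    directions: np.ndarray
    oscillation_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, float).ravel()
        self.directions = np.asarray(self.directions, float)
        if self.directions.shape != (self.b_values.size, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.b_values.size} b-values"
            )
        dwi = self.b_values > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("directions must be unit vectors where b > 0")

    @property
    def n_images(self) -> int:
        return self.b_values.size

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.b_values[self.b_values > 0])

    def select(self, shell: float | None) -> np.ndarray:
        """Boolean selector for b == 0 plus the given shell (or all)."""
        if shell is None:
            return np.ones(self.n_images, bool)
        return (self.b_values == 0) | np.isclose(self.b_values, shell)


@dataclass
class ParameterMaps:
    """Container for derived maps; entries are None when not computed."""

    MTR: np.ndarray | None = None
    MD: np.ndarray | None = None
    FA: np.ndarray | None = None
    D_R: np.ndarray | None = None
    MK: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# MTR
# --------------------------------------------------------------------------

def compute_mtr(
    M0: np.ndarray, Mt: np.ndarray, mask: np.ndarray, eps: float = 1e-12
) -> ParameterMaps:
    """Magnetization transfer ratio, ``MTR = (M0 - Mt) / M0``.

    Voxels with ``M0 <= eps`` are flagged invalid and removed from the
    returned ``valid_mask`` rather than producing infinities.
    """
    M0 = np.asarray(M0, float)
    Mt = np.asarray(Mt, float)
    mask = np.asarray(mask, bool)
    if M0.shape != Mt.shape or M0.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: M0 {M0.shape}, Mt {Mt.shape}, mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty mask")
    valid = mask & (M0 > eps)
    mtr = np.zeros_like(M0)
    mtr[valid] = (M0[valid] - Mt[valid]) / M0[valid]
    return ParameterMaps(MTR=mtr, valid_mask=valid)


# --------------------------------------------------------------------------
# Diffusion tensor (log-linear)
# --------------------------------------------------------------------------

def _tensor_design(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Design matrix for ln S = ln S0 - b g^T D g, columns:
    [1, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues ``(..., 3)`` (standard formula)."""
    evals = np.asarray(evals, float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5 * ((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals ** 2).sum(axis=-1))
    fa = np.zeros(evals.shape[:-1])
    nz = den > 0
    fa[nz] = num[nz] / den[nz]
    return np.clip(fa, 0.0, 1.0)


def fit_tensor_loglinear(
    dwis: np.ndarray,
    scheme: DiffusionScheme,
    mask: np.ndarray,
    shell: float | None = None,
) -> ParameterMaps:
    """Ordinary least-squares fit of the log-signal to a diffusion tensor.

    ``dwis`` is a 4D stack ``(x, y, z, n_images)`` matching the scheme.
    Voxels with any non-positive signal among the selected images are
    excluded from the valid mask.  When ``shell`` is given, only b = 0
    images and that shell are used.
    """
    dwis = np.asarray(dwis, float)
    mask = np.asarray(mask, bool)
    if dwis.shape[:3] != mask.shape or dwis.shape[3] != scheme.n_images:
        raise ValueError("dwis/scheme/mask dimensions disagree")
    sel = scheme.select(shell)
    b = scheme.b_values[sel]
    g = scheme.directions[sel]
    if not (b == 0).any():
        raise ValueError("scheme needs at least one b=0 image")
    n_dir = np.unique(np.round(g[b > 0], 6), axis=0).shape[0]
    if n_dir < 6:
        raise ValueError(
            f"scheme deficiency: {n_dir} unique directions in the selected "
            "shell, need >= 6 for a tensor fit"
        )
    X = _tensor_design(b, g)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("scheme deficiency: singular tensor design matrix")

    sig = dwis[..., sel][mask]                      # (V, m)
    valid_v = (sig > 0).all(axis=1)
    coef = np.zeros((sig.shape[0], 7))
    if valid_v.any():
        logs = np.log(sig[valid_v])
        coef[valid_v] = np.linalg.lstsq(X, logs.T, rcond=None)[0].T

    D = np.zeros((sig.shape[0], 3, 3))
    idx = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    for k, (i, j) in enumerate(idx):
        D[:, i, j] = coef[:, 1 + k]
        D[:, j, i] = coef[:, 1 + k]
    evals = np.linalg.eigvalsh(D)                   # ascending

    shp = mask.shape
    out_md = np.zeros(shp)
    out_fa = np.zeros(shp)
    out_dr = np.zeros(shp)
    out_ev = np.zeros(shp + (3,))
    md_v = evals.mean(axis=1)
    fa_v = fa_from_eigenvalues(evals)
    dr_v = evals[:, :2].mean(axis=1)                # two minor eigenvalues
    md_v[~valid_v] = 0.0
    fa_v[~valid_v] = 0.0
    dr_v[~valid_v] = 0.0
    out_md[mask] = md_v
    out_fa[mask] = fa_v
    out_dr[mask] = dr_v
    out_ev[mask] = np.where(valid_v[:, None], evals, 0.0)
    vmask = np.zeros(shp, bool)
    vmask[mask] = valid_v
    return ParameterMaps(MD=out_md, FA=out_fa, D_R=out_dr,
                         eigenvalues=out_ev, valid_mask=vmask)


# --------------------------------------------------------------------------
# Two-shell diffusion kurtosis
# --------------------------------------------------------------------------

def fit_dki_loglinear(
    dwis: np.ndarray,
    scheme: DiffusionScheme,
    mask: np.ndarray,
    k_floor: float = -1.0,
    k_ceiling: float = 10.0,
) -> ParameterMaps:
    """Per-direction two-shell kurtosis fit, averaged over directions.

    For each direction ``d`` shared by both shells, solves the exact
    2x2 linear system in ``(D_d, v_d)`` where ``v_d = D_d^2 K_d / 6``:

        ln(S_b / S0) = -b D_d + b^2 v_d

    then ``K_d = 6 v_d / D_d^2``.  MD and MK are the direction means;
    K is clamped to ``[k_floor, k_ceiling]`` and clamp counts reported
    in ``extras``.  Voxels with non-positive signals or non-positive
    fitted D in any direction are excluded from the valid mask.
    """
    dwis = np.asarray(dwis, float)
    mask = np.asarray(mask, bool)
    shells = scheme.shells
    if shells.size < 2:
        raise ValueError(f"kurtosis fit needs >= 2 nonzero shells, got {shells.size}")
    b1, b2 = float(shells[0]), float(shells[1])
    i0 = np.flatnonzero(scheme.b_values == 0)
    if i0.size == 0:
        raise ValueError("scheme needs a b=0 image")
    d1 = np.flatnonzero(np.isclose(scheme.b_values, b1))
    d2 = np.flatnonzero(np.isclose(scheme.b_values, b2))
    g1 = np.round(scheme.directions[d1], 6)
    g2 = np.round(scheme.directions[d2], 6)
    # match directions across shells
    order2 = []
    for g in g1:
        hits = np.flatnonzero((g2 == g).all(axis=1))
        if hits.size == 0:
            raise ValueError("shells do not share diffusion directions")
        order2.append(d2[hits[0]])
    d2 = np.asarray(order2)

    s0 = dwis[..., i0].mean(axis=3)[mask]           # (V,)
    s1 = dwis[..., d1][mask]                        # (V, n_dir)
    s2 = dwis[..., d2][mask]
    valid = (s0 > 0) & (s1 > 0).all(axis=1) & (s2 > 0).all(axis=1)

    V, n_dir = s1.shape
    Dd = np.zeros((V, n_dir))
    Kd = np.zeros((V, n_dir))
    if valid.any():
        y1 = np.log(s1[valid] / s0[valid, None])
        y2 = np.log(s2[valid] / s0[valid, None])
        # solve [-b1, b1^2; -b2, b2^2] (u, v)^T = (y1, y2)^T analytically
        det = -b1 * b2 ** 2 + b2 * b1 ** 2
        u = (b2 ** 2 * y1 - b1 ** 2 * y2) / det
        v = (b2 * y1 - b1 * y2) / det
        Dd[valid] = u
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(u > 0, 6.0 * v / u ** 2, 0.0)
        Kd[valid] = k
        valid &= (Dd > 0).all(axis=1)

    n_low = int((Kd[valid] < k_floor).sum())
    n_high = int((Kd[valid] > k_ceiling).sum())
    Kd = np.clip(Kd, k_floor, k_ceiling)

    shp = mask.shape
    md = np.zeros(shp)
    mk = np.zeros(shp)
    md_v = Dd.mean(axis=1)
    mk_v = Kd.mean(axis=1)
    md_v[~valid] = 0.0
    mk_v[~valid] = 0.0
    md[mask] = md_v
    mk[mask] = mk_v
    vmask = np.zeros(shp, bool)
    vmask[mask] = valid
    return ParameterMaps(
        MD=md, MK=mk, valid_mask=vmask,
        extras={"k_clamped_low": n_low, "k_clamped_high": n_high},
    )


# --------------------------------------------------------------------------
# Polynomial baselines
# --------------------------------------------------------------------------

def _poly_features(X: np.ndarray, order: int) -> tuple[np.ndarray, list[str]]:
    """Monomial features up to ``order`` (no intercept column).

    Order 1: x_i.  Order 2 adds x_i^2 and pairwise products x_i x_j.
    """
    n, C = X.shape
    feats = [X]
    names = [f"x{i}" for i in range(C)]
    if order == 2:
        feats.append(X ** 2)
        names += [f"x{i}^2" for i in range(C)]
        cols = []
        for i in range(C):
            for j in range(i + 1, C):
                cols.append(X[:, i] * X[:, j])
                names.append(f"x{i}*x{j}")
        if cols:
            feats.append(np.column_stack(cols))
    return np.concatenate(feats, axis=1), names


@dataclass
class PolynomialBaseline:
    """Fitted polynomial regression from channel signals to intensity.

    Coefficients are stored in original signal units, one per monomial
    feature (see ``feature_names``), plus an intercept.
    """

    order: int
    n_channels: int
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]
    channel_labels: list[str] | None = None
    training_residual: float = 0.0

    @property
    def linear_weights(self) -> np.ndarray:
        """First-order coefficients, one per channel."""
        return self.coefficients[: self.n_channels]

    def predict(self, inputs: np.ndarray,
                channel_labels: list[str] | None = None) -> np.ndarray:
        """Evaluate on signals of shape ``(..., C)``.

        When both the model and the call carry channel labels, channels
        are matched by label, so a permuted channel order still yields
        the identical map.
        """
        inputs = np.asarray(inputs, float)
        if inputs.shape[-1] != self.n_channels:
            raise ValueError(
                f"model expects {self.n_channels} channels, "
                f"got {inputs.shape[-1]}"
            )
        if channel_labels is not None and self.channel_labels is not None:
            if sorted(channel_labels) != sorted(self.channel_labels):
                raise ValueError("channel label sets differ")
            perm = [channel_labels.index(lbl) for lbl in self.channel_labels]
            inputs = inputs[..., perm]
        flat = inputs.reshape(-1, self.n_channels)
        F, _ = _poly_features(flat, self.order)
        y = F @ self.coefficients + self.intercept
        return y.reshape(inputs.shape[:-1])


def polynomial_baseline_fit(
    inputs: np.ndarray,
    target: np.ndarray,
    order: int = 1,
    channel_labels: list[str] | None = None,
) -> PolynomialBaseline:
    """Ordinary least squares of target intensity on channel monomials.

    ``inputs`` is ``(n_voxels, C)``; ``target`` is ``(n_voxels,)``.
    Features are standardized internally for conditioning; returned
    coefficients are mapped back to original units.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    X = np.asarray(inputs, float)
    y = np.asarray(target, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("inputs must be (n_voxels, C) matching target length")
    F, names = _poly_features(X, order)
    n, p = F.shape
    if n <= p + 1:
        raise ValueError(
            f"underdetermined fit: {n} voxels for {p + 1} coefficients"
        )
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    ok = sd > 0
    Fz = np.zeros_like(F)
    Fz[:, ok] = (F[:, ok] - mu[ok]) / sd[ok]
    A = np.column_stack([np.ones(n), Fz])
    rank = np.linalg.matrix_rank(A)
    if rank < 1 + int(ok.sum()):
        dep = [names[i] for i in range(p) if not ok[i]]
        raise ValueError(
            "rank-deficient polynomial design "
            f"(rank {rank} of {1 + int(ok.sum())}); "
            f"constant/collinear features: {dep or 'collinear combination'}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    coef = np.zeros(p)
    coef[ok] = beta[1:][ok] / sd[ok]
    intercept = float(beta[0] - (coef[ok] * mu[ok]).sum())
    resid = float(np.sqrt(np.mean((A @ beta - y) ** 2)))
    return PolynomialBaseline(
        order=order,
        n_channels=X.shape[1],
        coefficients=coef,
        intercept=intercept,
        feature_names=names,
        channel_labels=list(channel_labels) if channel_labels else None,
        training_residual=resid,
    )


def polynomial_baseline_predict(
    model: PolynomialBaseline,
    inputs: np.ndarray,
    channel_labels: list[str] | None = None,
) -> np.ndarray:
    """Functional alias for :meth:`PolynomialBaseline.predict`."""
    return model.predict(inputs, channel_labels)
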