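"""Forward head model and minimum-norm / sLORETA inverse.

The forward model is an analytic multi-shell spherical conductor
(default three shells: brain, skull, scalp).  For each spherical
harmonic degree ``n`` the potential in every shell is a combination of
``r^n`` and ``r^-(n+1)`` terms; matching potential and radial current
at each interface and imposing zero current through the scalp yields a
per-degree transfer scalar ``g_n`` multiplying the free-medium dipole
expansion.  For a homogeneous sphere ``g_n = (2n+1)/n``, which the
solver reproduces and the tests assert.

The inverse is the classical minimum-norm kernel
``K = R Gᵀ (G R Gᵀ + λ² C)⁻¹`` with identity source prior ``R``,
followed by sLORETA standardization: each source's 3×3 resolution
block ``(K G)_jj`` whitens its current estimate.  For a noiseless
single dipole the standardized power peaks exactly at the true grid
point (zero localization error), which is this module's primary test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import EpochSet, Montage

__all__ = [
    "ShellModel",
    "SourceGrid",
    "LeadField",
    "NoiseCovariance",
    "InverseOperator",
    "REGIONS",
    "build_leadfield",
    "estimate_noise_cov",
    "make_inverse",
    "apply_inverse",
    "parcellate",
]

REGIONS = (
    "medial_parietal",
    "medial_prefrontal",
    "cuneus",
    "lingual",
    "cingulate",
    "temporal_l",
    "temporal_r",
    "parietal_l",
    "parietal_r",
    "occipital",
    "frontal",
    "other",
)


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell conductor geometry.

    Radii are outer shell radii in head-radius units (scalp = 1);
    conductivities are relative (brain : skull : scalp defaults to
    1 : 1/80 : 1).
    """

    radii: tuple[float, ...] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, ...] = (1.0, 1.0 / 80.0, 1.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        s = np.asarray(self.conductivities, float)
        if r.shape != s.shape:
            raise ValueError("radii and conductivities must pair up")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("shell radii must be strictly increasing and positive")
        if np.any(s <= 0):
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class SourceGrid:
    """Dipole grid: positions inside the brain shell plus region tags."""

    positions: np.ndarray  # (n_sources, 3), head-radius units
    regions: np.ndarray  # (n_sources,) strings from REGIONS

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class LeadField:
    """Forward gain: channels × sources × 3 Cartesian moment components.

    Rows are average-referenced, so each (source, orientation) column
    sums to zero over channels.
    """

    gain: np.ndarray  # (n_channels, n_sources, 3)
    grid: SourceGrid
    shells: ShellModel
    montage_ref: str = "montage62"

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def gain2d(self) -> np.ndarray:
        """Gain reshaped to (channels, sources*3)."""
        g = self.gain
        return g.reshape(g.shape[0], -1)


@dataclass(frozen=True)
class NoiseCovariance:
    matrix: np.ndarray
    n_samples_used: int
    regularization: float


@dataclass(frozen=True)
class InverseOperator:
    """Minimum-norm kernel plus sLORETA standardization blocks."""

    kernel: np.ndarray  # (n_sources*3, n_channels)
    standardization: np.ndarray  # (n_sources, 3, 3) whitening matrices
    lambda2: float
    orientation_mode: str
    grid: SourceGrid
    montage_ref: str = "montage62"

    @property
    def n_sources(self) -> int:
        return self.grid.n_sources


# ---------------------------------------------------------------------------
# forward model


def _shell_transfer(n_max: int, shells: ShellModel) -> np.ndarray:
    """Per-degree transfer scalars g_n, n = 1..n_max.

    g_n is the ratio of total scalp potential to the primary (free
    medium) ``r^-(n+1)`` term at the scalp for harmonic degree n,
    obtained by solving the radial boundary-value problem across the
    shells.  Homogeneous limit: g_n = (2n+1)/n.
    """
    radii = np.asarray(shells.radii, float)
    sig = np.asarray(shells.conductivities, float)
    S = len(radii)
    g = np.empty(n_max)
    for n in range(1, n_max + 1):
        m = 2 * S - 1  # unknowns: A_1, then (A_j, B_j) for j = 2..S
        A = np.zeros((m, m))
        rhs = np.zeros(m)

        def a_col(j: int) -> int:  # index of A_j
            return 0 if j == 1 else 2 * j - 3

        def b_col(j: int) -> int:  # index of B_j (j >= 2)
            return 2 * j - 2

        row = 0
        for j in range(1, S):  # interface between shell j and j+1 at radii[j-1]
            r = radii[j - 1]
            # potential continuity
            A[row, a_col(j)] = r**n
            if j > 1:
                A[row, b_col(j)] = r ** -(n + 1)
            A[row, a_col(j + 1)] = -(r**n)
            A[row, b_col(j + 1)] = -(r ** -(n + 1))
            if j == 1:
                rhs[row] = -(r ** -(n + 1))  # primary term lives in shell 1
            row += 1
            # radial current continuity  sigma * dV/dr
            A[row, a_col(j)] = sig[j - 1] * n * r ** (n - 1)
            if j > 1:
                A[row, b_col(j)] = -sig[j - 1] * (n + 1) * r ** -(n + 2)
            A[row, a_col(j + 1)] = -sig[j] * n * r ** (n - 1)
            A[row, b_col(j + 1)] = sig[j] * (n + 1) * r ** -(n + 2)
            if j == 1:
                rhs[row] = sig[0] * (n + 1) * r ** -(n + 2)
            row += 1
        # outer boundary: no current through the scalp surface
        rO = radii[-1]
        A[row, a_col(S)] = n * rO ** (n - 1)
        if S > 1:
            A[row, b_col(S)] = -(n + 1) * rO ** -(n + 2)
        else:
            # single shell: A_1 only; primary supplies the B-type term
            rhs[row] = (n + 1) * rO ** -(n + 2)
        sol = np.linalg.solve(A, rhs)
        if S > 1:
            total = sol[a_col(S)] * rO**n + sol[b_col(S)] * rO ** -(n + 1)
        else:
            total = sol[0] * rO**n + rO ** -(n + 1)
        g[n - 1] = total / rO ** -(n + 1)
    return g


def _legendre_sums(
    x: np.ndarray, b: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate Σ g_n b^(n-1) n P_n(x) and Σ g_n b^(n-1) P_n'(x).

    ``x``: (E, Q) cosines between electrode and source directions;
    ``b``: (Q,) source eccentricities; ``g``: (n_max,) transfer scalars.
    Recurrences: Bonnet for P_n; P_n' = P_(n-2)' + (2n-1) P_(n-1).
    """
    n_max = len(g)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_prev = np.zeros_like(x)  # P_0'
    dp_cur = np.ones_like(x)  # P_1'
    bpow = np.ones_like(b)  # b^(n-1)
    sumA = np.zeros_like(x)
    sumB = np.zeros_like(x)
    for n in range(1, n_max + 1):
        if n > 1:
            p_next = ((2 * n - 1) * x * p_cur - (n - 1) * p_prev) / n
            dp_next = dp_prev + (2 * n - 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            bpow = bpow * b
        coef = g[n - 1] * bpow
        sumA += coef * n * p_cur
        sumB += coef * dp_cur
    return sumA, sumB


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions via the golden-angle lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _tag_region(direction: np.ndarray) -> str:
    """Coarse anatomical sector for a unit direction.

    Axes: +x right, +y anterior, +z superior.  The sectors carry the
    anatomical vocabulary used to report source-level effects (medial
    parietal/prefrontal, cuneus, lingual, cingulate, ...); boundaries
    are simple angular rules, not anatomy.
    """
    x, y, z = direction
    medial = abs(x) < 0.30
    if medial and y > 0.45 and z > 0.10:
        return "medial_prefrontal"
    if medial and y < -0.30 and z > 0.45:
        return "medial_parietal"
    if medial and y < -0.45 and 0.0 < z <= 0.45:
        return "cuneus"
    if medial and y < -0.35 and z <= 0.0:
        return "lingual"
    if abs(x) < 0.22 and -0.30 <= y <= 0.45 and z > 0.25:
        return "cingulate"
    if y < -0.60:
        return "occipital"
    if abs(x) > 0.55 and z < 0.25:
        return "temporal_r" if x > 0 else "temporal_l"
    if z > 0.25 and y < -0.05:
        return "parietal_r" if x > 0 else "parietal_l"
    if y > 0.15:
        return "frontal"
    return "other"


def make_source_grid(
    n_sources: int = 642,
    eccentricities: tuple[float, ...] = (0.40, 0.58, 0.74),
    brain_radius: float = 0.87,
) -> SourceGrid:
    """Fibonacci-lattice grid on concentric shells inside the brain.

    ``eccentricities`` are shell radii in head-radius units; sources are
    allocated to shells proportionally to shell area (r²).
    """
    ecc = np.asarray(eccentricities, float)
    if np.any(ecc >= brain_radius):
        raise ValueError("source shells must lie strictly inside the brain shell")
    weights = ecc**2 / np.sum(ecc**2)
    counts = np.maximum(1, np.round(weights * n_sources).astype(int))
    counts[-1] += n_sources - counts.sum()
    pos_parts = []
    for r, c in zip(ecc, counts):
        pos_parts.append(_fibonacci_sphere(int(c)) * r)
    pos = np.vstack(pos_parts)
    dirs = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    regions = np.array([_tag_region(d) for d in dirs], dtype=object)
    return SourceGrid(positions=pos, regions=regions)


def build_leadfield(
    montage: Montage,
    n_sources: int = 642,
    shells: ShellModel = ShellModel(),
    n_terms: int = 60,
    grid: SourceGrid | None = None,
) -> LeadField:
    """Analytic spherical-head lead field, average-referenced.

    Gain units are arbitrary-but-linear: scalp potential for a unit
    dipole moment.  Rows are projected onto the average reference, so
    every column of :attr:`LeadField.gain2d` sums to zero.
    """
    if grid is None:
        if n_sources < 50:
            raise ValueError("n_sources must be at least 50")
        grid = make_source_grid(n_sources)
    pos = grid.positions
    if np.any(np.linalg.norm(pos, axis=1) >= shells.radii[0]):
        raise ValueError("sources must lie strictly inside the innermost shell")
    g = _shell_transfer(n_terms, shells)
    elec = montage.positions  # (E, 3) on unit sphere
    b = np.linalg.norm(pos, axis=1)  # (Q,)
    # guard b=0 (center source): direction undefined; use +z, b^0 = 1 handled
    with np.errstate(invalid="ignore"):
        rhat = np.where(b[:, None] > 0, pos / np.where(b[:, None] == 0, 1, b[:, None]), [0, 0, 1.0])
    x = elec @ rhat.T  # (E, Q) cos angle
    sumA, sumB = _legendre_sums(x, b, g)
    sigma1 = shells.conductivities[0]
    # v(e, q, :) = (sumA * rhat + sumB * (elec - x rhat)) / (4 pi sigma1)
    gain = (
        sumA[:, :, None] * rhat[None, :, :]
        + sumB[:, :, None] * (elec[:, None, :] - x[:, :, None] * rhat[None, :, :])
    ) / (4.0 * np.pi * sigma1)
    gain = gain - gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain=gain, grid=grid, shells=shells)


# ---------------------------------------------------------------------------
# inverse


def estimate_noise_cov(
    es: EpochSet,
    window_ms: tuple[float, float] = (-1000.0, 0.0),
    regularization: float = 0.1,
) -> NoiseCovariance:
    """Empirical channel covariance over a window, concatenated trials.

    Diagonal loading adds ``regularization × mean(diag)`` to the
    diagonal; if there are fewer samples than channels and no loading
    was requested, loading is forced (with a warning) so the matrix
    stays positive definite.
    """
    mask = es.time_mask(window_ms)
    if not mask.any():
        raise ValueError(f"noise window {window_ms} outside epoch extent")
    seg = es.data[:, :, mask]  # (trials, ch, t)
    ns = seg.shape[0] * seg.shape[2]
    flat = seg.transpose(1, 0, 2).reshape(es.n_channels, ns)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / max(ns - 1, 1)
    if ns < es.n_channels and regularization == 0.0:
        warnings.warn(
            "fewer noise samples than channels; forcing diagonal loading",
            stacklevel=2,
        )
        regularization = 0.1
    mean_diag = float(np.mean(np.diag(cov)))
    if mean_diag == 0.0:
        mean_diag = 1.0  # zero data: loading-only diagonal
    cov = cov + regularization * mean_diag * np.eye(es.n_channels)
    return NoiseCovariance(matrix=cov, n_samples_used=ns, regularization=regularization)


def make_inverse(
    leadfield: LeadField,
    noise_cov: NoiseCovariance,
    lambda2: float,
    orientation_mode: str = "free",
) -> InverseOperator:
    """Minimum-norm kernel with sLORETA standardization blocks.

    ``kernel = Gᵀ (G Gᵀ + λ² C)⁻¹`` (identity source prior, no depth
    weighting); the per-source 3×3 blocks of the resolution matrix
    ``K G`` define the sLORETA whitening applied by
    :func:`apply_inverse`.
    """
    if lambda2 <= 0:
        raise ValueError("lambda2 must be positive")
    C = np.asarray(noise_cov.matrix, float)
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("noise covariance must be symmetric")
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-10 * max(evals.max(), 1.0):
        raise ValueError("noise covariance must be positive semidefinite")
    G = leadfield.gain2d  # (ch, 3Q)
    M = G @ G.T + lambda2 * C
    # average-referenced G and C share the null vector 1: pinv inverts on
    # the orthogonal complement.
    Minv = np.linalg.pinv(M, hermitian=True)
    K = G.T @ Minv  # (3Q, ch)
    Q = leadfield.grid.n_sources
    Kblk = K.reshape(Q, 3, -1)  # (Q, 3, ch)
    Gblk = leadfield.gain  # (ch, Q, 3)
    res = np.einsum("qac,cqb->qab", Kblk, Gblk)  # (Q, 3, 3) resolution blocks
    res = 0.5 * (res + res.transpose(0, 2, 1))
    w, V = np.linalg.eigh(res)
    w = np.maximum(w, 1e-12 * np.maximum(w.max(axis=1, keepdims=True), 1e-300))
    std = np.einsum("qab,qb,qcb->qac", V, 1.0 / np.sqrt(w), V)  # res^(-1/2)
    return InverseOperator(
        kernel=K,
        standardization=std,
        lambda2=float(lambda2),
        orientation_mode=orientation_mode,
        grid=leadfield.grid,
        montage_ref=leadfield.montage_ref,
    )


def auto_lambda2(leadfield: LeadField, noise_cov: NoiseCovariance, snr: float = 3.0) -> float:
    """λ² from the SNR heuristic, scaled to the gain/covariance units.

    λ² = trace(G Gᵀ) / (SNR² · trace(C)) makes the regularizer
    commensurate with the signal term for unit-variance sources.
    """
    G = leadfield.gain2d
    return float(np.sum(G * G) / (snr**2 * np.trace(noise_cov.matrix)))


def standardized_power(inv: InverseOperator, y: np.ndarray) -> np.ndarray:
    """Per-source sLORETA power for one sensor vector ``y`` (channels,)."""
    z = (inv.kernel @ y).reshape(inv.n_sources, 3)
    zs = np.einsum("qab,qb->qa", inv.standardization, z)
    return np.sum(zs * zs, axis=1)


def apply_inverse(es: EpochSet, inv: InverseOperator) -> EpochSet:
    """Map sensor epochs to source space.

    Free-orientation estimates are standardized per source (sLORETA
    whitening) and collapsed to a scalar by the orientation norm, so
    the output is nonnegative source activity per trial × source ×
    sample.
    """
    if es.space != "sensor":
        raise ValueError("apply_inverse expects sensor-space epochs")
    if es.n_channels != inv.kernel.shape[1]:
        raise ValueError(
            f"channel axis {es.n_channels} does not match inverse kernel "
            f"({inv.kernel.shape[1]} channels)"
        )
    nt, nc, ns = es.data.shape
    Q = inv.n_sources
    Kblk = inv.kernel.reshape(Q, 3, -1)
    W = inv.standardization
    WK = np.einsum("qab,qbc->qac", W, Kblk)  # (Q, 3, ch) standardized kernel
    # one GEMM over all trials: (3Q, ch) @ (ch, trials*samples)
    z = (WK.reshape(3 * Q, nc) @ es.data.transpose(1, 0, 2).reshape(nc, nt * ns))
    z = z.reshape(Q, 3, nt, ns)
    out = np.sqrt(np.einsum("qant,qant->qnt", z, z)).transpose(1, 0, 2)
    return EpochSet(
        data=out,
        fs=es.fs,
        t0_offset_ms=es.t0_offset_ms,
        labels=es.labels.copy(),
        meta=es.meta.copy(),
        montage_ref=f"grid{Q}",
        space="source",
        channel_names=None,
    )


def apply_inverse_vector(es: EpochSet, inv: InverseOperator) -> np.ndarray:
    """Unstandardized vector estimates (trials, sources, 3, samples).

    Exposes the linear minimum-norm stage (before the standardization
    norm), which is additive across inputs.
    """
    nt, _, ns = es.data.shape
    Q = inv.n_sources
    out = np.empty((nt, Q, 3, ns))
    Kblk = inv.kernel.reshape(Q, 3, -1)
    for i in range(nt):
        out[i] = np.einsum("qac,cs->qas", Kblk, es.data[i])
    return out


def parcellate(es_source: EpochSet, grid: SourceGrid) -> EpochSet:
    """Average source activity within each region tag.

    Output channels are the distinct region tags in canonical order
    (:data:`REGIONS` order, restricted to tags present on the grid).
    """
    if es_source.space != "source":
        raise ValueError("parcellate expects source-space epochs")
    if es_source.n_channels != grid.n_sources:
        raise ValueError("source axis does not match grid")
    present = [r for r in REGIONS if r in set(grid.regions)]
    out = np.empty((es_source.n_trials, len(present), es_source.n_samples))
    for k, reg in enumerate(present):
        sel = grid.regions == reg
        out[:, k, :] = es_source.data[:, sel, :].mean(axis=1)
    return replace(
        es_source,
        data=out,
        meta=es_source.meta.copy(),
        montage_ref=f"parcels{len(present)}",
        channel_names=tuple(present),
    )
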