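"""Elliptic Fourier descriptors and the eigenciona shape spaces.

A closed body outline is represented by its elliptic Fourier descriptors:
for harmonic n the coefficient quadruple (aₙ, bₙ, cₙ, dₙ) parameterizes an
ellipse whose superposition reconstructs the contour.  Coefficients are
computed exactly for piecewise-linear contours (closed-form segment
integration of the Fourier integrals, after Kuhl & Giardina) at order 30
(120 coefficients), then normalized for rotation/phase, size and
left–right mirroring.  The rotation-invariant amplitude spectrum
Aₙ = √(aₙ² + bₙ² + cₙ² + dₙ²) is truncated to the smallest harmonic count
carrying ≥ 99.9% of the squared-amplitude energy (10 on reference data).

PCA of the z-scored amplitude spectra yields the *eigencionas* — the
static postural modes EC1..ECk retaining ≥ 85% of the variance — and PCA
of within-animal frame-to-frame amplitude derivatives yields the dynamic
modes dEC1..dECk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .bodyplan import BodyPlan

__all__ = [
    "EFDSet", "ShapeSpace", "ContourRejection",
    "contour_from_landmarks", "efd_coefficients", "normalize_efd",
    "amplitude_spectrum", "choose_harmonics", "reconstruct",
    "reconstruction_error", "fit_shape_space", "project",
    "amplitude_derivatives",
]


@dataclass
class ContourRejection:
    """A frame excluded from shape analysis, with the reason."""
    frame: int
    reason: str  # "incomplete" | "geometrically impossible"


@dataclass
class EFDSet:
    """Per-frame EFD coefficients, (n_frames, order, 4) as (aₙ, bₙ, cₙ, dₙ)."""
    coefficients: np.ndarray
    order: int = 30
    normalized: bool = False
    frames: np.ndarray | None = None   # original frame indices of the rows


@dataclass
class ShapeSpace:
    """A fitted eigenciona basis (static or dynamic)."""
    kind: str                       # {"static", "dynamic"}
    mean: np.ndarray                # feature means (pre-z-scoring)
    scale: np.ndarray               # feature sds (pre-z-scoring)
    loadings: np.ndarray            # (k, n_features) orthonormal rows
    explained_variance_fraction: np.ndarray  # all n_features fractions
    k: int
    feature_names: list = field(default_factory=list)


# --------------------------------------------------------------------------
# contours

def contour_from_landmarks(coords: np.ndarray, plan: BodyPlan,
                           frame: int = 0):
    """Ordered closed outline of one frame, or a :class:`ContourRejection`.

    Frames with any NaN vertex are rejected as incomplete; self-
    intersecting outlines as geometrically impossible.
    """
    pts = np.asarray(coords, dtype=float)[list(plan.body_polygon)]
    if not np.all(np.isfinite(pts)):
        return ContourRejection(frame, "incomplete")
    if not Polygon(pts).is_valid:
        return ContourRejection(frame, "geometrically impossible")
    return pts


# --------------------------------------------------------------------------
# Kuhl-Giardina coefficients (exact piecewise-linear integration)

def efd_coefficients(contour: np.ndarray, order: int = 30) -> np.ndarray:
    """Elliptic Fourier coefficients of a closed polygonal contour.

    Returns (order, 4) rows (aₙ, bₙ, cₙ, dₙ).  The contour is traversed at
    uniform speed along each chord; the Fourier integrals are evaluated in
    closed form per segment (no resampling), so the result is exact for
    the polygon up to floating point.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("contour must be (V, 2) with V >= 3")
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)                 # (V, 2) segment steps
    dt = np.linalg.norm(d, axis=1)              # chord lengths
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    T = dt.sum()
    if T == 0:
        raise ValueError("zero-perimeter contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])  # cumulative chord length

    n = np.arange(1, order + 1)[:, None]        # (order, 1)
    w = 2.0 * np.pi * n / T
    cos_t = np.cos(w * t[None, :])              # (order, V+1)
    sin_t = np.sin(w * t[None, :])
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi ** 2)

    dx_dt = (d[:, 0] / dt)[None, :]
    dy_dt = (d[:, 1] / dt)[None, :]
    a = const * np.sum(dx_dt * dcos, axis=1)
    b = const * np.sum(dx_dt * dsin, axis=1)
    c = const * np.sum(dy_dt * dcos, axis=1)
    dd = const * np.sum(dy_dt * dsin, axis=1)
    return np.stack([a, b, c, dd], axis=1)


def efd_locus(contour: np.ndarray) -> np.ndarray:
    """DC component (A0, C0): the curve-length centroid of the contour."""
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.linalg.norm(d, axis=1)
    keep = dt > 0
    mid = (closed[:-1][keep] + closed[1:][keep]) / 2.0
    return (mid * dt[keep, None]).sum(axis=0) / dt[keep].sum()


def normalize_efd(coeffs: np.ndarray) -> np.ndarray:
    """Rotation/phase, size and mirror normalization (Kuhl–Giardina).

    The parameter phase is rotated so the first harmonic starts on its
    major axis; the spatial frame is rotated onto that axis; all
    coefficients are divided by the first-harmonic semi-major axis (so
    |a₁| = 1); and if the first-harmonic minor-axis coefficient d₁ is
    negative the contour is reflected (cₙ, dₙ → −cₙ, −dₙ), removing
    left–right mirror ambiguity.  Amplitudes are invariant to every step
    except the scale division.
    """
    c = np.array(coeffs, dtype=float)
    a1, b1, c1, d1 = c[0]
    denom = a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)
    n = np.arange(1, len(c) + 1)
    cos_nt, sin_nt = np.cos(n * theta), np.sin(n * theta)
    # phase rotation: [[a b],[c d]] @ [[cos, -sin],[sin, cos]] per harmonic
    a, b, cc, d = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    a2 = a * cos_nt + b * sin_nt
    b2 = -a * sin_nt + b * cos_nt
    c2 = cc * cos_nt + d * sin_nt
    d2 = -cc * sin_nt + d * cos_nt
    psi = np.arctan2(c2[0], a2[0])
    cp, sp = np.cos(psi), np.sin(psi)
    a3 = cp * a2 + sp * c2
    b3 = cp * b2 + sp * d2
    c3 = -sp * a2 + cp * c2
    d3 = -sp * b2 + cp * d2
    scale = abs(a3[0])
    if scale == 0:
        raise ValueError("degenerate first harmonic")
    out = np.stack([a3, b3, c3, d3], axis=1) / scale
    if out[0, 0] < 0:  # fix semi-major sign so a1 = +1
        out[:, 0] *= -1
        out[:, 1] *= -1
        out[:, 2] *= -1
        out[:, 3] *= -1
    if out[0, 3] < 0:  # mirror correction
        out[:, 2] *= -1
        out[:, 3] *= -1
    return out


def amplitude_spectrum(coeffs: np.ndarray, n_keep: int = 10) -> np.ndarray:
    """Per-harmonic amplitudes Aₙ = √(aₙ²+bₙ²+cₙ²+dₙ²), first ``n_keep``."""
    c = np.asarray(coeffs, dtype=float)
    amps = np.sqrt((c ** 2).sum(axis=-1))
    return amps[..., :n_keep]


def choose_harmonics(spectra: np.ndarray, energy: float = 0.999) -> int:
    """Smallest n whose frame-averaged cumulative energy fraction ≥ ``energy``.

    ``spectra`` is (n_frames, order) of full amplitude spectra; energy is
    the squared-amplitude fraction Σ₁..ₙAᵢ² / Σ₁..orderAᵢ², averaged over
    frames.
    """
    A2 = np.asarray(spectra, dtype=float) ** 2
    frac = np.cumsum(A2, axis=1) / A2.sum(axis=1, keepdims=True)
    mean_frac = frac.mean(axis=0)
    hit = np.nonzero(mean_frac >= energy - 1e-12)[0]
    return int(hit[0]) + 1 if len(hit) else A2.shape[1]


def reconstruct(coeffs: np.ndarray, n_harmonics: int | None = None,
                n_points: int = 400, locus: np.ndarray | None = None) -> np.ndarray:
    """Inverse Fourier series sampled at ``n_points`` along the contour."""
    c = np.asarray(coeffs, dtype=float)
    if n_harmonics is None:
        n_harmonics = len(c)
    if n_harmonics > len(c):
        raise ValueError("n_harmonics exceeds the coefficient order")
    t = np.linspace(0, 1, n_points, endpoint=False)
    n = np.arange(1, n_harmonics + 1)[:, None]
    cos_t = np.cos(2 * np.pi * n * t[None, :])
    sin_t = np.sin(2 * np.pi * n * t[None, :])
    x = c[:n_harmonics, 0] @ cos_t + c[:n_harmonics, 1] @ sin_t
    y = c[:n_harmonics, 2] @ cos_t + c[:n_harmonics, 3] @ sin_t
    pts = np.stack([x, y], axis=1)
    if locus is not None:
        pts = pts + np.asarray(locus)[None, :]
    return pts


def reconstruction_error(contour: np.ndarray, coeffs: np.ndarray,
                         n_harmonics: int | None = None,
                         n_points: int = 400) -> float:
    """Mean nearest-point distance from the original vertices to the
    reconstructed curve, as percent of the original perimeter."""
    pts = np.asarray(contour, dtype=float)
    recon = reconstruct(coeffs, n_harmonics, n_points, locus=efd_locus(pts))
    d = np.linalg.norm(pts[:, None, :] - recon[None, :, :], axis=2).min(axis=1)
    closed = np.vstack([pts, pts[:1]])
    perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
    return float(100.0 * d.mean() / perimeter)


# --------------------------------------------------------------------------
# eigenciona shape spaces

def fit_shape_space(features: np.ndarray, min_var: float = 0.85,
                    kind: str = "static",
                    feature_names: list | None = None) -> ShapeSpace:
    """PCA of z-scored features; retain the smallest k with cum. var ≥ min_var.

    Rows with NaN (e.g. masked derivative boundaries) are dropped for the
    fit; constant features are dropped with a warning.  Component signs
    are fixed so each loading's largest-|entry| is positive.
    """
    X = np.asarray(features, dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more frames than features to fit a shape space")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    const = scale <= 1e-12
    if np.any(const):
        import warnings
        warnings.warn(f"dropping {int(const.sum())} constant feature(s) before z-scoring")
        scale = np.where(const, 1.0, scale)
    Z = (X - mean) / scale
    cov = np.cov(Z.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    loadings = evecs[:, order].T            # rows = components
    # deterministic sign: largest-|loading| entry positive
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    frac = evals / evals.sum()
    k = int(np.searchsorted(np.cumsum(frac), min_var - 1e-12) + 1)
    names = feature_names or [f"A{i + 1}" for i in range(X.shape[1])]
    return ShapeSpace(kind=kind, mean=mean, scale=scale, loadings=loadings,
                      explained_variance_fraction=frac, k=k, feature_names=names)


def project(features: np.ndarray, space: ShapeSpace,
            n_components: int | None = None) -> np.ndarray:
    """Eigenciona score trajectories: loadings · z-scored features."""
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != len(space.mean):
        raise ValueError(f"expected {len(space.mean)} features, got {X.shape[-1]}")
    k = space.k if n_components is None else n_components
    Z = (X - space.mean) / space.scale
    return Z @ space.loadings[:k].T


def state_summary(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Mean ± SEM of each component per behavioral state."""
    out = {}
    for state in np.unique(labels):
        sel = scores[labels == state]
        sem = sel.std(axis=0, ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else np.zeros(scores.shape[1])
        out[str(state)] = {"mean": sel.mean(axis=0), "sem": sem, "n": len(sel)}
    return out


def amplitude_derivatives(spectra: np.ndarray,
                          animal_ids: np.ndarray | None = None) -> np.ndarray:
    """Within-animal first differences Aₙ(t) − Aₙ(t−1).

    The first frame of each animal is NaN (masked boundary); no
    cross-animal differencing.
    """
    A = np.asarray(spectra, dtype=float)
    d = np.full_like(A, np.nan)
    d[1:] = A[1:] - A[:-1]
    if animal_ids is not None:
        ids = np.asarray(animal_ids)
        boundary = np.ones(len(ids), dtype=bool)
        boundary[1:] = ids[1:] != ids[:-1]
        d[boundary] = np.nan
    return d


def frame_spectra(coords: np.ndarray, plan: BodyPlan, order: int = 30,
                  n_keep: int | None = None):
    """EFD amplitude spectra for every valid frame of a coordinate stack.

    Returns ``(spectra, frames, rejections)`` where ``frames`` holds the
    original indices of accepted rows.
    """
    spectra, frames, rejections = [], [], []
    for t in range(coords.shape[0]):
        contour = contour_from_landmarks(coords[t], plan, frame=t)
        if isinstance(contour, ContourRejection):
            rejections.append(contour)
            continue
        coeffs = normalize_efd(efd_coefficients(contour, order))
        spectra.append(amplitude_spectrum(coeffs, n_keep or order))
        frames.append(t)
    return (np.asarray(spectra, dtype=float),
            np.asarray(frames, dtype=int), rejections)
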