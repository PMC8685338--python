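"""Functional preprocessing on volumes and surfaces.

Stages: initial-volume dropping, mid-thickness construction, trilinear
volume-to-surface sampling given a world->voxel affine, nuisance regression
(white-matter/CSF means plus the 24-parameter motion expansion), and
band-pass filtering.

Affine convention: world coordinates are mm RAS; voxel indices are 0-based
and continuous, with voxel centers at integer indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .mesh import CortexMask, TriangleMesh

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceTimeSeries",
    "NuisanceSet",
    "midthickness",
    "vol_to_surf",
    "friston24",
    "nuisance_regress",
    "bandpass",
    "drop_initial_volumes",
]


@dataclass(frozen=True)
class SurfaceTimeSeries:
    """Per-vertex signal matrix ``data`` (V, T) bound to a mesh, with TR in seconds."""

    data: np.ndarray
    mesh: TriangleMesh
    tr: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2:
            raise ValueError("data must be (V, T)")
        if d.shape[0] != self.mesh.n_vertices:
            raise ValueError(
                f"row count {d.shape[0]} != mesh vertex count {self.mesh.n_vertices}"
            )
        if d.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not self.tr > 0:
            raise ValueError("TR must be > 0")
        object.__setattr__(self, "data", d)

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class NuisanceSet:
    """Nuisance inputs: 6 rigid-body motion parameters plus WM and CSF mean series.

    ``motion`` is (6, T): three translations (mm) then three rotations.
    """

    motion: np.ndarray
    wm_mean: np.ndarray
    csf_mean: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.motion, dtype=np.float64))
        wm = np.asarray(self.wm_mean, dtype=np.float64).ravel()
        csf = np.asarray(self.csf_mean, dtype=np.float64).ravel()
        if m.shape[0] != 6:
            raise ValueError(f"motion must be (6, T), got {m.shape}")
        t = m.shape[1]
        if wm.shape[0] != t or csf.shape[0] != t:
            raise ValueError("wm_mean/csf_mean length must match motion T")
        object.__setattr__(self, "motion", m)
        object.__setattr__(self, "wm_mean", wm)
        object.__setattr__(self, "csf_mean", csf)

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[1]


def midthickness(white: TriangleMesh, pial: TriangleMesh) -> TriangleMesh:
    """Per-vertex midpoint surface between topologically identical white and pial meshes."""
    if white.n_vertices != pial.n_vertices or not np.array_equal(
        white.triangles, pial.triangles
    ):
        raise ValueError("white and pial meshes must share an identical triangle list")
    return TriangleMesh(
        (white.vertices + pial.vertices) / 2.0, white.triangles, white.hemisphere
    )


def vol_to_surf(
    volume: np.ndarray,
    affine_world_to_voxel: np.ndarray,
    surface: TriangleMesh,
    tr: float = 1.0,
    oob_policy: str = "mask",
) -> tuple[SurfaceTimeSeries, CortexMask]:
    """Sample a 4D volume (X, Y, Z, T) at surface vertices by trilinear interpolation.

    Each vertex's world coordinate is mapped through the affine to a
    continuous 0-based voxel index. Vertices falling outside the grid are
    handled per ``oob_policy``: ``"mask"`` (default) marks them excluded in
    the returned mask and warns; ``"fail"`` raises.

    Trilinear sampling is exact for fields affine in world coordinates,
    which is the module's sharpest correctness oracle.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim == 3:
        vol = vol[..., None]
    if vol.ndim != 4:
        raise ValueError("volume must be 3D or 4D (X, Y, Z, T)")
    aff = np.asarray(affine_world_to_voxel, dtype=np.float64)
    if aff.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(aff)) < 1e-12:
        raise ValueError("affine is singular")

    homo = np.column_stack([surface.vertices, np.ones(surface.n_vertices)])
    ijk = (homo @ aff.T)[:, :3]

    shape = np.array(vol.shape[:3], dtype=float)
    inside = np.all((ijk >= 0) & (ijk <= shape - 1), axis=1)
    if not inside.all():
        n_out = int((~inside).sum())
        if oob_policy == "fail":
            raise ValueError(f"{n_out} vertices map outside the volume grid")
        if oob_policy != "mask":
            raise ValueError(f"unknown oob_policy {oob_policy!r}")
        warnings.warn(
            f"{n_out} vertices outside the field of view were masked out",
            stacklevel=2,
        )
    if not inside.any():
        raise ValueError("no vertex maps inside the volume grid")

    t_len = vol.shape[3]
    data = np.zeros((surface.n_vertices, t_len))
    coords = ijk.T  # (3, V)
    for t in range(t_len):
        data[:, t] = ndimage.map_coordinates(
            vol[..., t], coords, order=1, mode="nearest"
        )
    data[~inside] = 0.0
    return SurfaceTimeSeries(data, surface, tr), CortexMask(inside)


def friston24(motion: np.ndarray) -> np.ndarray:
    """24-parameter motion expansion: [R(t), R(t)^2, R(t-1), R(t-1)^2].

    Lagged rows are zero-filled at t=0. Input is (6, T); output (24, T).
    """
    m = np.atleast_2d(np.asarray(motion, dtype=np.float64))
    if m.shape[0] != 6:
        raise ValueError(f"expected 6 motion parameters, got {m.shape[0]}")
    if m.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    lag = np.zeros_like(m)
    lag[:, 1:] = m[:, :-1]
    return np.vstack([m, m**2, lag, lag**2])


def _clean_design(regressors: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Drop all-zero columns; return design and indices of retained columns."""
    keep = [j for j in range(regressors.shape[1])
            if np.any(regressors[:, j] != 0.0)]
    return regressors[:, keep], keep


def nuisance_regress(
    ts: SurfaceTimeSeries, nuisance: NuisanceSet
) -> SurfaceTimeSeries:
    """OLS residuals of each vertex series on [intercept, Friston-24, WM, CSF].

    The global signal is deliberately not a regressor. Constant-zero
    nuisance columns are dropped; remaining rank deficiency is an error
    naming the collinear columns.
    """
    t_len = ts.n_timepoints
    if nuisance.n_timepoints != t_len:
        raise ValueError(
            f"nuisance length {nuisance.n_timepoints} != time series length {t_len}"
        )
    names = (
        ["intercept"]
        + [f"friston24_{i}" for i in range(24)]
        + ["wm_mean", "csf_mean"]
    )
    design = np.column_stack(
        [np.ones(t_len), friston24(nuisance.motion).T,
         nuisance.wm_mean, nuisance.csf_mean]
    )
    design, kept = _clean_design(design)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns involved in the dependency for the error message
        bad = []
        cols_so_far = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([cols_so_far, design[:, j]])
            if np.linalg.matrix_rank(cand) == cols_so_far.shape[1]:
                bad.append(names[kept[j]])
            else:
                cols_so_far = cand
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data.T - design @ beta
    return replace(ts, data=resid.T)


def bandpass(
    ts: SurfaceTimeSeries,
    low: float,
    high: float,
    method: str = "fft",
    order: int = 4,
) -> SurfaceTimeSeries:
    """Retain spectral content in [low, high] Hz.

    ``method="fft"`` (default) applies an ideal mask on the discrete Fourier
    transform: bins with low <= f <= high are kept, all others (including
    DC when low > 0) zeroed. ``method="butterworth"`` applies a zero-phase
    Butterworth filter of the given order instead.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz >= Nyquist {nyquist} Hz at TR={ts.tr}")
    if method == "fft":
        freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.tr)
        spectrum = np.fft.rfft(ts.data, axis=1)
        keep = (freqs >= low) & (freqs <= high)
        spectrum[:, ~keep] = 0.0
        out = np.fft.irfft(spectrum, n=ts.n_timepoints, axis=1)
    elif method == "butterworth":
        wn = [max(low, 1e-9) / nyquist, high / nyquist]
        sos = signal.butter(order, wn, btype="bandpass", output="sos")
        out = signal.sosfiltfilt(sos, ts.data, axis=1)
    else:
        raise ValueError(f"unknown bandpass method {method!r}")
    return replace(ts, data=out)


def drop_initial_volumes(data, n_drop: int):
    """Drop the first ``n_drop`` frames of a SurfaceTimeSeries or a 4D array."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if isinstance(data, SurfaceTimeSeries):
        if n_drop >= data.n_timepoints:
            raise ValueError(
                f"cannot drop {n_drop} of {data.n_timepoints} volumes"
            )
        return replace(data, data=data.data[:, n_drop:])
    arr = np.asarray(data)
    if n_drop >= arr.shape[-1]:
        raise ValueError(f"cannot drop {n_drop} of {arr.shape[-1]} volumes")
    return arr[..., n_drop:]
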