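"""Synthetic spherical-head MEG: geometry, source dynamics, recordings, atlases.

Emulates a resting-state MEG session at desk scale: radial magnetometers on
the upper hemisphere of a 12 cm sphere, tangential dipoles on an 8 cm source
sphere, band-limited (1-100 Hz) distributed source dynamics with local
spatial correlation, additive sensor noise at a controlled SNR in dB, and
sensor-only empty-room recordings.

Every function is a pure function of its inputs and seed.
"""

from __future__ import annotations

import numpy as np
import scipy.signal
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from .datatypes import (
    Atlas,
    HeadModel,
    Leadfield,
    Recording,
    RecordingKind,
    SimulationConfig,
    SourceActivity,
)

SENSOR_RADIUS_M = 0.12
SOURCE_RADIUS_M = 0.08
#: Baseline empty-room sensor noise, tesla (order of magnitude of MEG noise floors).
EMPTY_ROOM_NOISE_T = 1e-13


def _fibonacci_sphere(n: int, hemisphere: bool = False) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    if hemisphere:
        z = (i + 0.5) / n  # z in (0, 1): upper hemisphere
    else:
        z = 1 - (2 * i + 1) / n  # z in (-1, 1): full sphere
    rho = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _tangential_orientations(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vectors tangential to the sphere at each position."""
    radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    rand = rng.standard_normal(positions.shape)
    tang = rand - np.einsum("ij,ij->i", rand, radial)[:, None] * radial
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    # A random vector is almost surely not parallel to the radial direction,
    # but guard the degenerate draw anyway.
    bad = norms[:, 0] < 1e-12
    while np.any(bad):
        rand = rng.standard_normal((bad.sum(), 3))
        t = rand - np.einsum("ij,ij->i", rand, radial[bad])[:, None] * radial[bad]
        tang[bad] = t
        norms = np.linalg.norm(tang, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-12
    return tang / norms


def build_spherical_head(config: SimulationConfig) -> HeadModel:
    """Construct sensor and source geometry on concentric spheres.

    Sensors are radial magnetometers quasi-uniform on the upper hemisphere
    at 0.12 m; dipoles are quasi-uniform on a full sphere at 0.08 m with
    random tangential orientations. The dipole neighbor graph is the
    symmetrized k-nearest-neighbor graph (k = ``spatial_corr_neighbors``).
    """
    if config.n_sensors < 8 or config.n_dipoles < 8:
        raise ValueError("need at least 8 sensors and 8 dipoles")
    rng = np.random.default_rng(config.seed)

    sensor_pos = SENSOR_RADIUS_M * _fibonacci_sphere(config.n_sensors, hemisphere=True)
    sensor_ori = sensor_pos / np.linalg.norm(sensor_pos, axis=1, keepdims=True)
    dipole_pos = SOURCE_RADIUS_M * _fibonacci_sphere(config.n_dipoles)
    dipole_ori = _tangential_orientations(dipole_pos, rng)

    k = config.spatial_corr_neighbors
    if k > 0:
        knn = kneighbors_graph(dipole_pos, n_neighbors=min(k, config.n_dipoles - 1), mode="connectivity")
        adj = knn.maximum(knn.T)  # symmetrize
        adj.data[:] = 1.0
    else:
        adj = sp.csr_matrix((config.n_dipoles, config.n_dipoles))
    return HeadModel(
        sensor_positions=sensor_pos,
        sensor_orientations=sensor_ori,
        dipole_positions=dipole_pos,
        dipole_orientations=dipole_ori,
        neighbor_graph=sp.csr_matrix(adj),
    )


def simulate_sources(head: HeadModel, config: SimulationConfig) -> SourceActivity:
    """Band-limited Gaussian source dynamics with local spatial correlation.

    Each dipole time course is band-pass-filtered white Gaussian noise
    (4th-order Butterworth, two-pass, band clipped at Nyquist), then one
    smoothing pass averages each dipole with its graph neighbors to induce
    the local spatial correlation responsible for realistic leakage.
    Amplitudes are on the order of 10 nA*m per dipole.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_t = config.n_samples
    raw = rng.standard_normal((head.n_dipoles, n_t))

    nyq = config.fs / 2
    lo, hi = config.band_hz
    hi = min(hi, 0.99 * nyq)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, raw, axis=1)

    if config.spatial_corr_neighbors > 0 and head.neighbor_graph.nnz:
        adj = head.neighbor_graph + sp.eye(head.n_dipoles, format="csr")
        weights = 1.0 / np.asarray(adj.sum(axis=1)).ravel()
        data = sp.diags(weights) @ (adj @ data)

    data -= data.mean(axis=1, keepdims=True)
    return SourceActivity(data=1e-8 * data, fs=config.fs)


def simulate_recording(
    leadfield: Leadfield,
    sources: SourceActivity,
    snr_db: float | None,
    seed: int,
) -> Recording:
    """Project sources to sensors and add white noise at an exact SNR in dB.

    The noise standard deviation is scaled against the realized (sample)
    mean channel variance of the signal, so that
    ``10*log10(mean_var(L s) / sigma_noise^2) == snr_db`` exactly for this
    realization. ``snr_db=None`` disables noise.
    """
    if leadfield.n_dipoles != sources.n_dipoles:
        raise ValueError("leadfield and sources disagree on dipole count")
    signal = leadfield.matrix @ sources.data
    if snr_db is None or np.isinf(snr_db):
        return Recording(data=signal, fs=sources.fs, kind=RecordingKind.RESTING, seed=seed)
    sig_var = signal.var(axis=1, ddof=0).mean()
    if sig_var == 0:
        raise ValueError("zero-variance signal: SNR is undefined")
    noise_var = sig_var / 10 ** (snr_db / 10)
    rng = np.random.default_rng(seed)
    noise = np.sqrt(noise_var) * rng.standard_normal(signal.shape)
    return Recording(data=signal + noise, fs=sources.fs, kind=RecordingKind.RESTING, seed=seed)


def simulate_empty_room(
    n_sensors: int,
    duration_s: float,
    fs: float,
    seed: int,
    common_mode_rank: int = 3,
) -> Recording:
    """Sensor-only noise recording with an optional low-rank common mode.

    White Gaussian sensor noise plus ``common_mode_rank`` shared spatial
    patterns (each 3x the white-noise amplitude), so the empty-room
    covariance is not perfectly diagonal — a stand-in for environmental
    hall noise. Set ``common_mode_rank=0`` for pure white noise.
    """
    if n_sensors <= 0 or duration_s <= 0 or fs <= 0:
        raise ValueError("arguments must be positive")
    rng = np.random.default_rng(seed)
    n_t = int(round(duration_s * fs))
    data = EMPTY_ROOM_NOISE_T * rng.standard_normal((n_sensors, n_t))
    if common_mode_rank > 0:
        patterns = np.linalg.qr(rng.standard_normal((n_sensors, common_mode_rank)))[0]
        courses = 3.0 * EMPTY_ROOM_NOISE_T * np.sqrt(n_sensors) * rng.standard_normal((common_mode_rank, n_t))
        data = data + patterns @ courses
    return Recording(data=data, fs=fs, kind=RecordingKind.EMPTY_ROOM, seed=seed)


def build_synthetic_atlas(head: HeadModel, n_rois: int, n_clusters: int, seed: int) -> Atlas:
    """Partition dipoles into contiguous ROIs, and ROIs into clusters.

    Spatial k-means on dipole positions yields ROIs (contiguity follows
    from nearest-centroid assignment on the convex source sphere); k-means
    on ROI centroids yields the cluster grouping. ROI adjacency is derived
    from the dipole neighbor graph. Empty ROIs trigger an internal reseed
    (up to 10 attempts).
    """
    if not (n_clusters <= n_rois <= head.n_dipoles):
        raise ValueError("need n_clusters <= n_rois <= n_dipoles")
    for attempt in range(10):
        km = KMeans(n_clusters=n_rois, n_init=3, random_state=seed + attempt)
        labels = km.fit_predict(head.dipole_positions) + 1
        if np.unique(labels).size == n_rois:
            break
    else:
        raise RuntimeError("could not build an atlas with all ROIs non-empty")
    centroids = km.cluster_centers_
    for attempt in range(10):
        kmc = KMeans(n_clusters=n_clusters, n_init=3, random_state=seed + 1000 + attempt)
        roi_cluster = kmc.fit_predict(centroids) + 1
        if np.unique(roi_cluster).size == n_clusters:
            break
    else:
        raise RuntimeError("could not group ROIs into non-empty clusters")

    coo = head.neighbor_graph.tocoo()
    adjacency = {
        (int(min(labels[i], labels[j])), int(max(labels[i], labels[j])))
        for i, j in zip(coo.row, coo.col)
        if labels[i] != labels[j]
    }
    return Atlas(dipole_roi=labels, roi_cluster=roi_cluster, roi_adjacency=adjacency)
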