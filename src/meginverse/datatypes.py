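"""Core containers for the MEG source-reconstruction evaluation pipeline.

The data model mirrors the linear forward problem ``x = L s + eta``:
a :class:`HeadModel` fixes the geometry, a :class:`Leadfield` holds the
forward matrix ``L`` (channels x dipoles), a :class:`Recording` is sensor
data ``x``, and an :class:`InverseOperator` is a spatial-filter matrix
``Phi`` mapping sensors back to dipoles (``s_hat = Phi x``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class RecordingKind(str, enum.Enum):
    RESTING = "resting"
    EMPTY_ROOM = "empty_room"


class Algorithm(str, enum.Enum):
    """The six linear inverse algorithms under evaluation."""

    LCMV = "lcmv"
    UNGMV = "ungmv"
    MNE = "mne"
    WMNE = "wmne"
    SLORETA = "sloreta"
    ELORETA = "eloreta"


ALL_ALGORITHMS: tuple[Algorithm, ...] = tuple(Algorithm)

#: Algorithms whose output is normalized (unit filter rows or unit theoretical
#: variance) and therefore not in units of current density.
NORMALIZED_ALGORITHMS = frozenset({Algorithm.UNGMV, Algorithm.SLORETA})


@dataclass
class HeadModel:
    """Sensor array and dipole source space on concentric spheres.

    Dipole orientations are tangential to the source sphere: radial dipoles
    inside a spherical conductor are magnetically silent, so tangential
    orientations guarantee no all-zero leadfield column.
    """

    sensor_positions: np.ndarray  # (n_sensors, 3), meters
    sensor_orientations: np.ndarray  # (n_sensors, 3), unit vectors
    dipole_positions: np.ndarray  # (n_dipoles, 3), meters
    dipole_orientations: np.ndarray  # (n_dipoles, 3), unit tangential vectors
    neighbor_graph: sp.csr_matrix  # symmetric 0/1 adjacency over dipoles
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
        self.dipole_positions = np.asarray(self.dipole_positions, dtype=float)
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        sens_r = np.linalg.norm(self.sensor_positions - self.sphere_center, axis=1)
        dip_r = np.linalg.norm(self.dipole_positions - self.sphere_center, axis=1)
        if dip_r.max() >= sens_r.min():
            raise ValueError("all dipoles must lie strictly inside the sensor shell")
        for name, arr in (("sensor", self.sensor_orientations), ("dipole", self.dipole_orientations)):
            norms = np.linalg.norm(arr, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError(f"{name} orientations must be unit norm")
        g = self.neighbor_graph
        if (g != g.T).nnz != 0:
            raise ValueError("neighbor graph must be symmetric")
        if g.diagonal().any():
            raise ValueError("neighbor graph must have no self-loops")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.dipole_positions.shape[0]


@dataclass
class Leadfield:
    """Forward matrix ``L`` (n_sensors x n_dipoles), tesla per ampere-meter."""

    matrix: np.ndarray
    channel_ids: np.ndarray | None = None
    dipole_ids: np.ndarray | None = None
    column_norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield contains non-finite entries")
        self.column_norms = np.linalg.norm(self.matrix, axis=0)
        zero = np.flatnonzero(self.column_norms == 0)
        if zero.size:
            raise ValueError(f"leadfield has all-zero columns at dipoles {zero.tolist()}")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.matrix.shape[0])
        if self.dipole_ids is None:
            self.dipole_ids = np.arange(self.matrix.shape[1])

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Recording:
    """Sensor time series (n_sensors x n_samples) with sampling rate in Hz."""

    data: np.ndarray
    fs: float
    kind: RecordingKind = RecordingKind.RESTING
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.kind = RecordingKind(self.kind)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("recording must be 2-D with at least 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SourceActivity:
    """Dipole current time courses (n_dipoles x n_samples), ampere-meter."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("source activity contains non-finite values")

    @property
    def n_dipoles(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic resting-state MEG simulation.

    Defaults emulate a desk-scale resting-state session: a 30 s epoch at
    256 Hz band-limited to 1-100 Hz, with local spatial correlation among
    neighboring dipoles and sensor noise at 2.5 dB SNR.
    """

    n_sensors: int = 120
    n_dipoles: int = 600
    duration_s: float = 30.0
    fs: float = 256.0
    band_hz: tuple[float, float] = (1.0, 100.0)
    spatial_corr_neighbors: int = 4
    snr_db: float = 2.5
    empty_room_common_mode_rank: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors <= 0 or self.n_dipoles <= 0:
            raise ValueError("sensor and dipole counts must be positive")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        lo, hi = self.band_hz
        if not (0 <= lo < hi):
            raise ValueError("band edges must satisfy 0 <= low < high")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class Atlas:
    """Dipole -> ROI and ROI -> cluster label maps with ROI adjacency.

    ROI and cluster ids are 1-based consecutive integers. Two ROIs are
    adjacent iff some dipole of one is a graph neighbor of a dipole of the
    other.
    """

    dipole_roi: np.ndarray  # (n_dipoles,) int, values in 1..n_rois
    roi_cluster: np.ndarray  # (n_rois,) int, values in 1..n_clusters
    roi_adjacency: set[tuple[int, int]] = field(default_factory=set)  # (a<b) pairs
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dipole_roi = np.asarray(self.dipole_roi, dtype=int)
        self.roi_cluster = np.asarray(self.roi_cluster, dtype=int)
        rois = np.unique(self.dipole_roi)
        if rois.min() < 1 or rois.max() > self.n_rois or rois.size != self.n_rois:
            raise ValueError("dipole_roi labels must cover 1..n_rois with no empty ROI")
        self.roi_adjacency = {(min(a, b), max(a, b)) for a, b in self.roi_adjacency if a != b}

    @property
    def n_dipoles(self) -> int:
        return self.dipole_roi.size

    @property
    def n_rois(self) -> int:
        return self.roi_cluster.size

    @property
    def n_clusters(self) -> int:
        return int(self.roi_cluster.max())

    def roi_members(self, roi: int) -> np.ndarray:
        return np.flatnonzero(self.dipole_roi == roi)

    def cluster_rois(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.roi_cluster == cluster) + 1


class NoiseSource(str, enum.Enum):
    IDENTITY = "identity"
    EMPTY_ROOM_SAMPLE = "empty_room_sample"


@dataclass
class NoiseModel:
    """Sensor-noise covariance ``C`` used to regularize the LSMN operators."""

    covariance: np.ndarray
    source: NoiseSource = NoiseSource.IDENTITY

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=float)
        if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise ValueError("noise covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(c).min()
        if eigmin < -1e-12 * np.trace(c):
            raise ValueError("noise covariance must be positive semidefinite")
        self.covariance = 0.5 * (c + c.T)

    @classmethod
    def identity(cls, n_channels: int) -> "NoiseModel":
        return cls(np.eye(n_channels), NoiseSource.IDENTITY)

    @classmethod
    def from_recording(cls, rec: Recording) -> "NoiseModel":
        data = rec.data - rec.data.mean(axis=1, keepdims=True)
        return cls(data @ data.T / (rec.n_samples - 1), NoiseSource.EMPTY_ROOM_SAMPLE)


@dataclass
class InverseOperator:
    """A spatial-filter matrix ``Phi`` (n_dipoles x n_sensors) plus metadata."""

    filters: np.ndarray
    algorithm: Algorithm
    lambda2: float = 0.0
    snr_db: float = np.nan
    prior_diag: np.ndarray | None = None  # diagonal of W (LSMN only)
    iterations: int | None = None  # eLORETA only
    converged: bool = True

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.algorithm = Algorithm(self.algorithm)
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("inverse operator contains non-finite entries")

    @property
    def n_dipoles(self) -> int:
        return self.filters.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.filters.shape[1]


@dataclass
class SourceEstimate:
    """Estimated dipole time courses ``s_hat = Phi x``."""

    data: np.ndarray
    algorithm: Algorithm
    fs: float
    units: str = "current_density"  # or "normalized" for sLORETA/UNGMV

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.algorithm = Algorithm(self.algorithm)

    @property
    def n_dipoles(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
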