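"""Cross-validated sensor variance explained (rCV2) and its empty-room ratio.

An inverse solution is scored by how well forward-mapping its source
estimate predicts held-out sensors: channels are randomly partitioned into
k folds; for each fold the operator is rebuilt from the training-channel
rows of the leadfield, sources are reconstructed from training channels
only, and the squared Pearson correlation between each test sensor's
recorded and predicted time series is averaged over all sensors and folds:

    rCV2 = (1/N_x) * sum_folds sum_{test in fold} corr(x_test, x_hat_test)^2

Because the score is correlation-based it is invariant to per-channel
amplitude rescalings, so normalized solutions (sLORETA, UNGMV) are
directly comparable with current-density ones. The same procedure applied
to an empty-room recording yields rER2, and the ratio rCV2/rER2 penalizes
algorithms that overfit non-brain signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Algorithm, Atlas, Leadfield, NoiseModel, Recording
from .inverse import build_operator, sample_covariance
from .parcellation import parcellate_rank1


@dataclass
class SensorPartition:
    """Balanced random partition of channel indices into k folds."""

    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        n = all_idx.size
        if np.unique(all_idx).size != n:
            raise ValueError("folds must be disjoint")
        if not np.array_equal(np.sort(all_idx), np.arange(n)):
            raise ValueError("folds must cover all channels")
        sizes = [f.size for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def n_channels(self) -> int:
        return sum(f.size for f in self.folds)


@dataclass
class AlgorithmSpec:
    """How to build one inverse operator inside the evaluation loop."""

    algorithm: Algorithm
    snr_db: float = 2.5
    lambda2: float | None = None  # explicit override (e.g. 0 = unregularized)
    wmne_exponent: float = 1.0

    def __post_init__(self) -> None:
        self.algorithm = Algorithm(self.algorithm)


@dataclass
class VarianceExplainedResult:
    r2_cv: float
    r2_er: float
    algorithm: Algorithm
    snr_db: float
    n_excluded_sensors: int = 0

    @property
    def ratio(self) -> float:
        if self.r2_er == 0:
            raise ZeroDivisionError("rER2 = 0: ratio undefined")
        return self.r2_cv / self.r2_er


def partition_sensors(n_channels: int, k: int, seed: int) -> SensorPartition:
    """Random balanced partition: ``n mod k`` folds get the larger size.

    The same partition must be reused across all algorithms evaluated on a
    given dataset so per-fold training sets are identical.
    """
    if k > n_channels:
        raise ValueError("cannot have more folds than channels")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_channels)
    base, extra = divmod(n_channels, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return SensorPartition(folds=folds, seed=seed)


def default_fold_count(n_channels: int) -> int:
    """Scale the fold count so folds hold ~10 channels (27 folds for 274)."""
    return max(2, round(n_channels / 10.15))


def _build_for_channels(
    spec: AlgorithmSpec, leadfield_rows: np.ndarray, rec_rows: np.ndarray
):
    """Build an operator restricted to a channel subset."""
    sub_lf = Leadfield(leadfield_rows)
    n = leadfield_rows.shape[0]
    if spec.algorithm in (Algorithm.LCMV, Algorithm.UNGMV):
        centered = rec_rows - rec_rows.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / (rec_rows.shape[1] - 1)
        return build_operator(spec.algorithm, sub_lf, spec.snr_db, data_cov=cov)
    noise = NoiseModel.identity(n)
    if spec.lambda2 is not None:
        from .inverse import (
            eloreta_operator,
            lsmn_operator,
            mne_weights,
            sloreta_operator,
            wmne_weights,
        )

        if spec.algorithm is Algorithm.MNE:
            return lsmn_operator(sub_lf, noise, mne_weights(sub_lf), spec.lambda2, spec.algorithm, spec.snr_db)
        if spec.algorithm is Algorithm.WMNE:
            return lsmn_operator(
                sub_lf, noise, wmne_weights(sub_lf, spec.wmne_exponent), spec.lambda2, spec.algorithm, spec.snr_db
            )
        if spec.algorithm is Algorithm.SLORETA:
            return sloreta_operator(sub_lf, noise, spec.lambda2, spec.snr_db)
        if spec.algorithm is Algorithm.ELORETA:
            return eloreta_operator(sub_lf, noise, spec.lambda2, snr_db=spec.snr_db)
        raise ValueError(f"lambda2 override unsupported for {spec.algorithm}")
    return build_operator(
        spec.algorithm, sub_lf, spec.snr_db, noise=noise, wmne_exponent=spec.wmne_exponent
    )


def _per_sensor_r2(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per channel; NaN where undefined."""
    xc = x - x.mean(axis=1, keepdims=True)
    pc = x_hat - x_hat.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc**2, axis=1))
    sp = np.sqrt(np.sum(pc**2, axis=1))
    out = np.full(x.shape[0], np.nan)
    ok = (sx > 0) & (sp > 0)
    out[ok] = (np.sum(xc * pc, axis=1)[ok] / (sx[ok] * sp[ok])) ** 2
    return out


def cross_validated_r2(
    rec: Recording,
    leadfield: Leadfield,
    spec: AlgorithmSpec,
    partition: SensorPartition,
    atlas: Atlas | None = None,
) -> tuple[float, int]:
    """Sensor-fold cross-validated variance explained.

    Returns ``(r2, n_excluded)`` where excluded sensors had zero-variance
    data or predictions. If ``atlas`` is given, the source estimate is
    replaced by its rank-1 per-ROI (first principal component)
    reconstruction before forward mapping.
    """
    if partition.n_channels != rec.n_channels or rec.n_channels != leadfield.n_sensors:
        raise ValueError("recording, leadfield and partition disagree on channels")
    all_r2 = []
    for fold in partition.folds:
        train = np.setdiff1d(np.arange(rec.n_channels), fold)
        op = _build_for_channels(spec, leadfield.matrix[train], rec.data[train])
        s_hat = op.filters @ rec.data[train]
        if atlas is not None:
            s_hat = parcellate_rank1(s_hat, atlas)
        x_hat = leadfield.matrix[fold] @ s_hat
        all_r2.append(_per_sensor_r2(rec.data[fold], x_hat))
    r2 = np.concatenate(all_r2)
    n_excluded = int(np.isnan(r2).sum())
    return float(np.nanmean(r2)), n_excluded


def in_sample_r2(
    rec: Recording, leadfield: Leadfield, spec: AlgorithmSpec, atlas: Atlas | None = None
) -> tuple[float, int]:
    """Variance explained without cross-validation (train = test = all
    channels); the construction behind the unregularized-MNE saturation
    argument (r2 = 1 on any full-row-rank data)."""
    op = _build_for_channels(spec, leadfield.matrix, rec.data)
    s_hat = op.filters @ rec.data
    if atlas is not None:
        s_hat = parcellate_rank1(s_hat, atlas)
    x_hat = leadfield.matrix @ s_hat
    r2 = _per_sensor_r2(rec.data, x_hat)
    return float(np.nanmean(r2)), int(np.isnan(r2).sum())


def ve_ratio(r2_cv: float, r2_er: float) -> float:
    """Headline score rCV2 / rER2 (overfit-corrected variance explained)."""
    if r2_er <= 0:
        raise ZeroDivisionError("rER2 must be positive to form the ratio")
    return r2_cv / r2_er


def variance_explained(
    resting: Recording,
    empty_room: Recording,
    leadfield: Leadfield,
    spec: AlgorithmSpec,
    partition: SensorPartition,
    atlas: Atlas | None = None,
) -> VarianceExplainedResult:
    """rCV2, rER2 and their ratio with one shared sensor partition.

    The resting and empty-room pipelines are code-identical: only the
    input recording differs.
    """
    r2_cv, excl_cv = cross_validated_r2(resting, leadfield, spec, partition, atlas)
    r2_er, excl_er = cross_validated_r2(empty_room, leadfield, spec, partition, atlas)
    return VarianceExplainedResult(
        r2_cv=r2_cv,
        r2_er=r2_er,
        algorithm=spec.algorithm,
        snr_db=spec.snr_db,
        n_excluded_sensors=excl_cv + excl_er,
    )
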