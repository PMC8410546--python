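"""The six linear inverse operators with a shared SNR-indexed regularization.

Two families are implemented:

* **LSMN** (least-squares minimum norm): MNE, wMNE, sLORETA, eLORETA.
  All share the kernel ``Phi = W L' (L W L' + lambda2 C)^+`` and differ in
  the diagonal source-covariance prior ``W`` (MNE: identity; wMNE: inverse
  leadfield column norms; eLORETA: fixed-point optimized) or in a
  post-hoc standardization (sLORETA).
* **Beamformers**: LCMV (unit gain, ``Phi_i l_i = 1``) and UNGMV (LCMV
  rows rescaled to unit Euclidean norm).

A single predicted-SNR knob (in dB) sets the regularization strength of
every algorithm: ``lambda2 = trace(L W L') / (trace(C) 10^(snr/10))`` for
LSMN operators and diagonal loading ``gamma = 10^(-snr/10)`` for the
beamformers.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    Algorithm,
    InverseOperator,
    Leadfield,
    NoiseModel,
    Recording,
    SourceEstimate,
    NORMALIZED_ALGORITHMS,
)

#: Relative cutoff for pseudo-inverses, as a fraction of the largest
#: singular value; keeps rank-deficient toy problems well-defined.
PINV_RTOL = 1e-12


def _pinv(a: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(a, rcond=PINV_RTOL)


def regularization_from_snr(
    leadfield: Leadfield, noise: NoiseModel, snr_db: float
) -> float:
    """Map a predicted SNR (dB, power scale) to a Tikhonov weight lambda2.

    ``lambda2 = trace(L L') / (trace(C) * 10^(snr_db/10))`` — the standard
    minimum-norm convention relating the regularization parameter to the
    assumed signal-to-noise power ratio. Strictly decreasing in snr_db.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    tr_c = np.trace(noise.covariance)
    if tr_c <= 0:
        raise ValueError("noise covariance must have positive trace")
    tr_l = np.sum(leadfield.matrix**2)
    if tr_l == 0:
        raise ValueError("leadfield is identically zero")
    return float(tr_l / (tr_c * 10 ** (snr_db / 10)))


def lsmn_operator(
    leadfield: Leadfield,
    noise: NoiseModel,
    prior_diag: np.ndarray,
    lambda2: float,
    algorithm: Algorithm = Algorithm.MNE,
    snr_db: float = np.nan,
) -> InverseOperator:
    """Regularized minimum-norm kernel ``Phi = W L' (L W L' + lambda2 C)^+``.

    With ``lambda2 = 0`` the kernel is computed through the Moore-Penrose
    pseudo-inverse of ``L W^{1/2}`` (numerically equivalent but far better
    conditioned than forming ``(L W L')^+`` explicitly).
    """
    prior_diag = np.asarray(prior_diag, dtype=float)
    if np.any(prior_diag <= 0):
        raise ValueError("prior diagonal must be strictly positive")
    l = leadfield.matrix
    if lambda2 == 0:
        w_half = np.sqrt(prior_diag)
        filters = w_half[:, None] * _pinv(l * w_half[None, :])
    else:
        lw = l * prior_diag[None, :]
        gram = lw @ l.T + lambda2 * noise.covariance
        filters = lw.T @ _pinv(gram)
    return InverseOperator(
        filters=filters,
        algorithm=algorithm,
        lambda2=float(lambda2),
        snr_db=snr_db,
        prior_diag=prior_diag,
    )


def mne_weights(leadfield: Leadfield) -> np.ndarray:
    """MNE prior: identity source covariance (all-ones diagonal)."""
    return np.ones(leadfield.n_dipoles)


def wmne_weights(leadfield: Leadfield, exponent: float = 1.0) -> np.ndarray:
    """Depth-weighted prior, inversely proportional to leadfield column norms.

    ``W_jj = ||L_j||^-exponent``, rescaled to unit mean so that the
    SNR-indexed lambda2 remains on the same scale as for MNE.
    """
    norms = leadfield.column_norms
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero leadfield column(s) at dipoles {zero.tolist()}")
    w = norms ** (-exponent)
    return w / w.mean()


def eloreta_weights(
    leadfield: Leadfield,
    noise: NoiseModel,
    lambda2: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, int, bool]:
    """Fixed-point optimization of the eLORETA source-covariance diagonal.

    Iterates ``M = (L W L' + lambda2 C)^+``, ``W_jj = (l_j' M l_j)^(-1/2)``
    from ``W = I`` until the maximum relative change in W drops below
    ``tol``. Returns ``(prior_diag, iterations, converged)``; on
    non-convergence a warning is issued rather than an exception.
    """
    l = leadfield.matrix
    w = np.ones(leadfield.n_dipoles)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gram = (l * w[None, :]) @ l.T + lambda2 * noise.covariance
        m = _pinv(gram)
        quad = np.einsum("ij,ij->j", l, m @ l)
        if np.any(quad <= 0):
            raise np.linalg.LinAlgError("non-positive quadratic form in eLORETA update")
        w_new = quad**-0.5
        rel = np.max(np.abs(w_new - w) / np.maximum(np.abs(w), 1e-300))
        w = w_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"eLORETA did not converge in {max_iter} iterations", RuntimeWarning)
    return w, it, converged


def eloreta_operator(
    leadfield: Leadfield,
    noise: NoiseModel,
    lambda2: float,
    tol: float = 1e-6,
    max_iter: int = 100,
    snr_db: float = np.nan,
) -> InverseOperator:
    """eLORETA: LSMN kernel at the converged fixed-point prior."""
    w, iterations, converged = eloreta_weights(leadfield, noise, lambda2, tol, max_iter)
    op = lsmn_operator(leadfield, noise, w, lambda2, Algorithm.ELORETA, snr_db)
    op.iterations = iterations
    op.converged = converged
    return op


def sloreta_operator(
    leadfield: Leadfield,
    noise: NoiseModel,
    lambda2: float,
    snr_db: float = np.nan,
) -> InverseOperator:
    """sLORETA: MNE kernel standardized to unit theoretical source variance.

    Row j of the MNE kernel is divided by
    ``sqrt([Phi_mne (L L' + lambda2 C) Phi_mne']_jj)``; the output is no
    longer in units of current density.
    """
    mne_op = lsmn_operator(leadfield, noise, mne_weights(leadfield), lambda2, Algorithm.MNE, snr_db)
    phi = mne_op.filters
    model_cov = leadfield.matrix @ leadfield.matrix.T + lambda2 * noise.covariance
    var = np.einsum("ij,ij->i", phi, phi @ model_cov)
    if np.any(var <= 0):
        raise np.linalg.LinAlgError("non-positive theoretical variance in sLORETA")
    return InverseOperator(
        filters=phi / np.sqrt(var)[:, None],
        algorithm=Algorithm.SLORETA,
        lambda2=float(lambda2),
        snr_db=snr_db,
        prior_diag=mne_op.prior_diag,
    )


def lcmv_operator(
    leadfield: Leadfield,
    data_cov: np.ndarray,
    gamma: float,
    snr_db: float = np.nan,
) -> InverseOperator:
    """LCMV beamformer: unit-gain minimum-variance spatial filters.

    ``Phi_j = (l_j' C_reg^-1 l_j)^-1 l_j' C_reg^-1`` with diagonal loading
    ``C_reg = C_x + gamma (trace(C_x)/N_x) I``. ``gamma`` is conventionally
    tied to the predicted SNR by ``gamma = 10^(-snr_db/10)``.
    """
    c = np.asarray(data_cov, dtype=float)
    n_x = c.shape[0]
    c_reg = c + gamma * (np.trace(c) / n_x) * np.eye(n_x)
    if gamma == 0 and np.linalg.matrix_rank(c_reg) < n_x:
        raise np.linalg.LinAlgError(
            "singular data covariance with gamma=0; add diagonal loading (gamma > 0)"
        )
    ci_l = np.linalg.solve(c_reg, leadfield.matrix)  # C_reg^-1 L
    gains = np.einsum("ij,ij->j", leadfield.matrix, ci_l)  # l_j' C^-1 l_j
    if np.any(gains <= 0):
        raise np.linalg.LinAlgError("non-positive beamformer gain denominator")
    filters = (ci_l / gains[None, :]).T
    return InverseOperator(
        filters=filters, algorithm=Algorithm.LCMV, lambda2=float(gamma), snr_db=snr_db
    )


def ungmv_operator(
    leadfield: Leadfield,
    data_cov: np.ndarray,
    gamma: float,
    snr_db: float = np.nan,
) -> InverseOperator:
    """Unit-noise-gain beamformer: LCMV rows rescaled to unit norm."""
    lcmv = lcmv_operator(leadfield, data_cov, gamma, snr_db)
    norms = np.linalg.norm(lcmv.filters, axis=1)
    if np.any(norms == 0):
        raise np.linalg.LinAlgError("zero-norm beamformer filter row")
    return InverseOperator(
        filters=lcmv.filters / norms[:, None],
        algorithm=Algorithm.UNGMV,
        lambda2=float(gamma),
        snr_db=snr_db,
    )


def apply_inverse(op: InverseOperator, rec: Recording) -> SourceEstimate:
    """Reconstruct source time courses: ``s_hat = Phi x``."""
    if op.n_sensors != rec.n_channels:
        raise ValueError(
            f"operator expects {op.n_sensors} channels, recording has {rec.n_channels}"
        )
    units = "normalized" if op.algorithm in NORMALIZED_ALGORITHMS else "current_density"
    return SourceEstimate(data=op.filters @ rec.data, algorithm=op.algorithm, fs=rec.fs, units=units)


def sample_covariance(rec: Recording) -> np.ndarray:
    """Unbiased sample covariance of a recording's channels."""
    centered = rec.data - rec.data.mean(axis=1, keepdims=True)
    return centered @ centered.T / (rec.n_samples - 1)


def build_operator(
    algorithm: Algorithm,
    leadfield: Leadfield,
    snr_db: float,
    noise: NoiseModel | None = None,
    data_cov: np.ndarray | None = None,
    wmne_exponent: float = 1.0,
) -> InverseOperator:
    """Construct any of the six operators at a common predicted SNR.

    Beamformers (LCMV/UNGMV) require ``data_cov``; LSMN solvers use
    ``noise`` (identity by default) through the SNR-indexed lambda2.
    """
    algorithm = Algorithm(algorithm)
    if algorithm in (Algorithm.LCMV, Algorithm.UNGMV):
        if data_cov is None:
            raise ValueError("beamformers require a data covariance")
        gamma = 10 ** (-snr_db / 10)
        fn = lcmv_operator if algorithm is Algorithm.LCMV else ungmv_operator
        return fn(leadfield, data_cov, gamma, snr_db=snr_db)
    if noise is None:
        noise = NoiseModel.identity(leadfield.n_sensors)
    lambda2 = regularization_from_snr(leadfield, noise, snr_db)
    if algorithm is Algorithm.MNE:
        return lsmn_operator(leadfield, noise, mne_weights(leadfield), lambda2, algorithm, snr_db)
    if algorithm is Algorithm.WMNE:
        w = wmne_weights(leadfield, wmne_exponent)
        return lsmn_operator(leadfield, noise, w, lambda2, algorithm, snr_db)
    if algorithm is Algorithm.SLORETA:
        return sloreta_operator(leadfield, noise, lambda2, snr_db)
    if algorithm is Algorithm.ELORETA:
        return eloreta_operator(leadfield, noise, lambda2, snr_db=snr_db)
    raise ValueError(f"unknown algorithm {algorithm}")
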