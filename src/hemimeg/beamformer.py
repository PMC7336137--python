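"""LCMV beamformer virtual-electrode reconstruction.

A linearly constrained minimum-variance (LCMV) beamformer passes signal
from a target source location with unit gain while minimising output
variance.  Given the broadband sensor covariance ``C`` and a lead field
``L`` (sensors x orientation components), the steps are:

1. covariance of the demeaned concatenation of all trials,
2. Tikhonov regularisation with a noise floor equal to a fraction
   (default 5%) of the mean covariance eigenvalue,
3. source covariance ``P(r) = (L^T C^-1 L)^-1``; the optimal source
   orientation is the eigenvector of ``P(r)`` with the largest eigenvalue
   (the max output-power criterion),
4. weights ``W = C^-1 l / (l^T C^-1 l)`` for ``l = L @ orientation``,
   which satisfy the unit-gain constraint ``W^T l = 1``,
5. virtual-electrode series ``V = B @ W`` per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps


# ---------------------------------------------------------------------------
# containers

@dataclass
class SensorTrialSet:
    """Sensor-level data: trials x sensors x samples at sampling rate fs."""

    data: np.ndarray
    fs: float
    trial_indices: np.ndarray | None = None  # original temporal trial indices

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if self.n_sensors < 10:
            raise ValueError("need at least 10 sensors")
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.n_trials)
        else:
            self.trial_indices = np.asarray(self.trial_indices, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def trial_length(self) -> float:
        return self.n_samples / self.fs

    def save(self, path: str | Path) -> None:
        _save_h5(path, self.data, self.fs, self.trial_indices, roi_ids=None)

    @classmethod
    def load(cls, path: str | Path) -> "SensorTrialSet":
        data, fs, idx, _ = _load_h5(path)
        return cls(data, fs, idx)


@dataclass
class VirtualElectrodeSet:
    """Reconstructed source series: ROI x trials x samples."""

    data: np.ndarray
    fs: float
    roi_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    trial_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be roi x trials x samples")
        if self.roi_ids is None:
            self.roi_ids = np.arange(1, self.data.shape[0] + 1)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.n_trials)
        else:
            self.trial_indices = np.asarray(self.trial_indices, dtype=int)

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def trial_length(self) -> float:
        return self.n_samples / self.fs

    def save(self, path: str | Path) -> None:
        _save_h5(path, self.data, self.fs, self.trial_indices, self.roi_ids)

    @classmethod
    def load(cls, path: str | Path) -> "VirtualElectrodeSet":
        data, fs, idx, roi_ids = _load_h5(path)
        return cls(data, fs, roi_ids, idx)

    def export_roi_tsv(self, roi_id: int, path: str | Path) -> None:
        """Write a single ROI's trials x samples series as TSV."""
        pos = int(np.flatnonzero(self.roi_ids == roi_id)[0])
        np.savetxt(path, self.data[pos], delimiter="\t")


def _save_h5(path, data, fs, trial_indices, roi_ids) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.attrs["fs"] = fs
        f.attrs["trial_length"] = data.shape[-1] / fs
        f.create_dataset("trial_indices", data=trial_indices)
        if roi_ids is not None:
            f.create_dataset("roi_ids", data=roi_ids)


def _load_h5(path):
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        idx = f["trial_indices"][()] if "trial_indices" in f else None
        roi_ids = f["roi_ids"][()] if "roi_ids" in f else None
    return data, fs, idx, roi_ids


@dataclass(frozen=True)
class LeadField:
    """Sensor response pattern of a unit source: M x p matrix, p orientations."""

    matrix: np.ndarray
    source_id: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("lead field must be 2-D (sensors x components)")
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("lead field is rank deficient")


@dataclass(frozen=True)
class CovarianceMatrix:
    matrix: np.ndarray
    regularized: bool = False
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class BeamformerWeights:
    weights: np.ndarray  # M
    orientation: np.ndarray  # p, unit norm
    source_cov: np.ndarray  # p x p, P(r)
    source_id: int = 0


# ---------------------------------------------------------------------------
# operations

def broadband_covariance(trials: SensorTrialSet) -> CovarianceMatrix:
    """Sample covariance of the demeaned concatenation of all trials.

    The per-sensor mean is removed over the whole concatenated window (one
    time window including all surviving trials), not per trial.
    """
    if trials.n_trials < 2:
        raise ValueError("need at least 2 trials for the data covariance")
    x = np.concatenate(list(trials.data), axis=-1)  # M x T
    if x.shape[1] < 2:
        raise ValueError("need more than one sample")
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / (x.shape[1] - 1)
    return CovarianceMatrix((cov + cov.T) / 2.0, regularized=False)


def regularize_covariance(
    cov: CovarianceMatrix, fraction: float = 0.05
) -> CovarianceMatrix:
    """Tikhonov regularisation: add fraction * mean(eigenvalues) to the diagonal.

    The mean eigenvalue equals trace/M, so every eigenvalue shifts up by
    exactly ``fraction * trace(C)/M`` and the result is positive definite
    for any PSD input with positive trace.
    """
    c = cov.matrix
    m = c.shape[0]
    floor = fraction * np.trace(c) / m
    return CovarianceMatrix(c + floor * np.eye(m), regularized=True, noise_floor=floor)


def optimal_orientation(
    lf: LeadField, cov_reg: CovarianceMatrix, criterion: str = "max_power"
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal source orientation from the beamformer source covariance.

    ``P(r) = (L^T C^-1 L)^-1``; the returned orientation is the unit
    eigenvector of ``P(r)`` with the largest eigenvalue, which maximises
    beamformer output power ``1 / (eta^T L^T C^-1 L eta)``.  The alternative
    ``criterion="min_power"`` selects the smallest eigenvalue instead.
    The eigenvector sign is fixed so its largest-magnitude component is
    positive.

    Returns (orientation, P) where P is the p x p source covariance.
    """
    c = cov_reg.matrix
    l = lf.matrix
    try:
        ci_l = np.linalg.solve(c, l)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance is singular; regularize first") from e
    gram = l.T @ ci_l
    gram = (gram + gram.T) / 2.0
    if np.linalg.cond(gram) > 1e12:
        raise ValueError("L^T C^-1 L is singular")
    p_r = np.linalg.inv(gram)
    p_r = (p_r + p_r.T) / 2.0
    evals, evecs = np.linalg.eigh(p_r)
    idx = -1 if criterion == "max_power" else 0
    if criterion not in ("max_power", "min_power"):
        raise ValueError("criterion must be 'max_power' or 'min_power'")
    eta = evecs[:, idx]
    k = int(np.argmax(np.abs(eta)))
    if eta[k] < 0:
        eta = -eta
    return eta, p_r


def compute_weights(
    lf: LeadField, orientation: np.ndarray, cov_reg: CovarianceMatrix
) -> BeamformerWeights:
    """Unit-gain LCMV weights ``W = C^-1 l / (l^T C^-1 l)``."""
    eta = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(eta) - 1.0) > 1e-6:
        raise ValueError("orientation must be unit norm")
    ell = lf.matrix @ eta
    ci_ell = np.linalg.solve(cov_reg.matrix, ell)
    denom = float(ell @ ci_ell)
    if denom <= 0:
        raise ValueError("l^T C^-1 l must be positive")
    w = ci_ell / denom
    gram = lf.matrix.T @ np.linalg.solve(cov_reg.matrix, lf.matrix)
    p_r = np.linalg.inv((gram + gram.T) / 2.0)
    return BeamformerWeights(w, eta, p_r, lf.source_id)


def reconstruct_ve(
    trials: SensorTrialSet, weights: list[BeamformerWeights]
) -> VirtualElectrodeSet:
    """Project sensor trials through the weights: V = B @ W per ROI, trial."""
    w = np.stack([bw.weights for bw in weights], axis=0)  # R x M
    if w.shape[1] != trials.n_sensors:
        raise ValueError("weights/sensor count mismatch")
    # data: trials x M x samples -> R x trials x samples
    ve = np.einsum("rm,tms->rts", w, trials.data)
    roi_ids = np.asarray([bw.source_id for bw in weights], dtype=int)
    return VirtualElectrodeSet(ve, trials.fs, roi_ids, trials.trial_indices)


def beamform(
    trials: SensorTrialSet,
    leadfields: list[LeadField],
    reg_fraction: float = 0.05,
    criterion: str = "max_power",
) -> VirtualElectrodeSet:
    """Full VE reconstruction: covariance, regularisation, per-ROI weights."""
    cov = regularize_covariance(broadband_covariance(trials), reg_fraction)
    ws = []
    for lf in leadfields:
        eta, _ = optimal_orientation(lf, cov, criterion)
        ws.append(compute_weights(lf, eta, cov))
    return reconstruct_ve(trials, ws)


def preprocess_broadband(
    trials: SensorTrialSet,
    band: tuple[float, float] = (0.1, 150.0),
    notches: tuple[float, ...] = (60.0, 120.0),
) -> SensorTrialSet:
    """Zero-phase broadband filtering of sensor trials.

    4th-order Butterworth band-pass plus 2nd-order band-stop at the mains
    frequency and its first harmonic, applied forward-backward
    (zero phase).  Notches above Nyquist are skipped.
    """
    nyq = trials.fs / 2.0
    lo, hi = band
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=trials.fs, output="sos")
    out = sps.sosfiltfilt(sos, trials.data, axis=-1)
    for f0 in notches:
        if f0 >= nyq:
            continue
        sos_n = sps.butter(
            2, [f0 - 1.0, f0 + 1.0], btype="bandstop", fs=trials.fs, output="sos"
        )
        out = sps.sosfiltfilt(sos_n, out, axis=-1)
    return SensorTrialSet(out, trials.fs, trials.trial_indices)
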