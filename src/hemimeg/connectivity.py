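"""Phase-lag-index connectivity from virtual-electrode trials.

Per trial, Hann-tapered discrete Fourier spectra (no zero padding) give
cross-spectra ``s_k(f) = X_i(f) conj(X_j(f))``.  Across the K trials the
phase-lag index family is:

* PLI   = |mean_k sgn(Im s_k)|
* wPLI  = |mean_k Im s_k| / mean_k |Im s_k|
* dwPLI = sum_{k != j} Im s_k Im s_j / sum_{k != j} |Im s_k Im s_j|

The debiased square estimator (dwPLI) removes the positive small-sample
bias of the squared wPLI by excluding same-trial products.  All three
return 0 in 0/0 cases (identical signals carry no lagged coupling).
Per-bin dwPLI values are averaged over closed frequency bands to build
symmetric, zero-diagonal weighted adjacency matrices; negative debiased
estimates are clipped to zero after band averaging so that graph measures
receive nonnegative weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BandSpec
from .beamformer import VirtualElectrodeSet

_ESTIMATORS = ("pli", "wpli", "dwpli")


@dataclass
class CrossSpectrumSet:
    """Cross-spectra: pairs x trials x frequency bins, with the bin grid."""

    values: np.ndarray  # complex
    freqs: np.ndarray
    pairs: list[tuple[int, int]]  # 0-based channel indices
    fs: float
    window: str = "hann"

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class ConnectivityMatrix:
    """Band-averaged weighted adjacency (symmetric, zero diagonal)."""

    matrix: np.ndarray
    band: BandSpec | None = None
    estimator: str = "dwpli"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        self.matrix = m

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.8g")

    @classmethod
    def load(cls, path, band: BandSpec | None = None) -> "ConnectivityMatrix":
        return cls(np.loadtxt(path, delimiter="\t"), band)


def segment_trials(
    ve: VirtualElectrodeSet, target_length: float
) -> VirtualElectrodeSet:
    """Regroup 3-s trials into longer trials of consecutive survivors.

    A 12-s trial is formed only from 4 *consecutive* surviving 3-s trials
    (consecutive original temporal indices); leftover trials are dropped.
    Trials already at the target length pass through unchanged.
    """
    cur = ve.trial_length
    # trial lengths are quantized to whole samples, so compare with a
    # half-sample tolerance rather than exact float equality
    tol = 0.5 / ve.fs
    if abs(cur - target_length) <= tol:
        return ve
    if target_length < cur - tol:
        raise ValueError("cannot shorten trials")
    ratio = target_length / cur
    k = int(round(ratio))
    if abs(k * cur - target_length) > k * tol:
        raise ValueError("target length must be a multiple of the trial length")
    idx = np.asarray(ve.trial_indices)
    groups: list[list[int]] = []
    run: list[int] = []
    for pos in range(len(idx)):
        if run and idx[pos] != idx[run[-1]] + 1:
            run = []
        run.append(pos)
        if len(run) == k:
            groups.append(run)
            run = []
    if not groups:
        raise ValueError(
            f"fewer than {k} consecutive trials; cannot form any "
            f"{target_length:g}-s trial"
        )
    data = np.stack(
        [
            np.concatenate([ve.data[:, p, :] for p in g], axis=-1)
            for g in groups
        ],
        axis=1,
    )
    return VirtualElectrodeSet(
        data, ve.fs, ve.roi_ids, np.arange(len(groups))
    )


def trial_cross_spectra(
    ve: VirtualElectrodeSet, pairs: list[tuple[int, int]]
) -> CrossSpectrumSet:
    """Hann-tapered per-trial cross-spectra for the requested channel pairs."""
    n = ve.n_samples
    for i, j in pairs:
        if not (0 <= i < ve.n_rois and 0 <= j < ve.n_rois):
            raise IndexError(f"pair ({i}, {j}) out of range")
    win = np.hanning(n)
    spec = np.fft.rfft(ve.data * win, axis=-1)  # roi x trials x bins
    freqs = np.fft.rfftfreq(n, 1.0 / ve.fs)
    vals = np.stack(
        [spec[i] * np.conj(spec[j]) for i, j in pairs], axis=0
    )
    return CrossSpectrumSet(vals, freqs, list(pairs), ve.fs)


def _pli(im: np.ndarray) -> np.ndarray:
    return np.abs(np.mean(np.sign(im), axis=-2))


def _wpli(im: np.ndarray) -> np.ndarray:
    num = np.abs(np.mean(im, axis=-2))
    den = np.mean(np.abs(im), axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _dwpli(im: np.ndarray) -> np.ndarray:
    # sum over ordered pairs k != j equals (sum)^2 - sum of squares
    s1 = np.sum(im, axis=-2)
    s2 = np.sum(im**2, axis=-2)
    sa = np.sum(np.abs(im), axis=-2)
    num = s1**2 - s2
    den = sa**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def phase_lag_indices(cs: CrossSpectrumSet, estimator: str = "dwpli") -> np.ndarray:
    """Per-bin connectivity values, shape pairs x bins (trials collapsed)."""
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}")
    im = np.imag(cs.values)  # pairs x trials x bins
    if estimator == "dwpli" and cs.n_trials < 2:
        raise ValueError("dwPLI needs at least 2 trials")
    if estimator == "pli":
        return _pli(im)
    if estimator == "wpli":
        return _wpli(im)
    return _dwpli(im)


def band_average(
    per_bin: np.ndarray, freqs: np.ndarray, band: BandSpec, trial_length: float
) -> np.ndarray:
    """Average per-bin values over the band's closed frequency interval."""
    spacing = freqs[1] - freqs[0]
    # allow the small spacing offset from sample-quantized trial lengths
    if abs(spacing - 1.0 / band.trial_length) > 1e-3 / band.trial_length:
        raise ValueError(
            f"band {band.name} requires {band.trial_length:g}-s trials "
            f"(bin spacing 1/{band.trial_length:g} Hz), got spacing {spacing:g} Hz"
        )
    mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return per_bin[..., mask].mean(axis=-1)


def band_adjacency(
    per_bin: np.ndarray,
    freqs: np.ndarray,
    pairs: list[tuple[int, int]],
    band: BandSpec,
    n_nodes: int,
    trial_length: float,
    estimator: str = "dwpli",
) -> ConnectivityMatrix:
    """Assemble a symmetric adjacency from per-pair band-averaged values.

    Negative (debiased) values are clipped to zero after averaging; the
    diagonal is zero.
    """
    vals = band_average(per_bin, freqs, band, trial_length)
    m = np.zeros((n_nodes, n_nodes))
    for (i, j), v in zip(pairs, vals):
        m[i, j] = m[j, i] = v
    np.clip(m, 0.0, None, out=m)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(m, band, estimator)


def connectivity_matrix(
    ve: VirtualElectrodeSet, band: BandSpec, estimator: str = "dwpli"
) -> ConnectivityMatrix:
    """Band-averaged all-pairs adjacency from VE trials.

    Trials are regrouped to the band's trial length first (12 s for delta),
    then per-bin estimates over the band's closed interval are averaged.
    Memory-light path: the imaginary cross-spectrum of all pairs is
    accumulated bin by bin.
    """
    ve_b = segment_trials(ve, band.trial_length)
    n = ve_b.n_samples
    r = ve_b.n_rois
    win = np.hanning(n)
    spec = np.fft.rfft(ve_b.data * win, axis=-1)  # r x trials x bins
    freqs = np.fft.rfftfreq(n, 1.0 / ve_b.fs)
    mask = (freqs >= band.f_low - 1e-12) & (freqs <= band.f_high + 1e-12)
    bins = np.flatnonzero(mask)
    if bins.size == 0:
        raise ValueError(f"no frequency bins inside band {band.name}")
    if estimator == "dwpli" and ve_b.n_trials < 2:
        raise ValueError("dwPLI needs at least 2 trials")
    acc = np.zeros((r, r))
    for b in bins:
        x = spec[:, :, b]  # r x trials
        im = np.einsum("it,jt->ijt", x.imag, x.real) - np.einsum(
            "it,jt->ijt", x.real, x.imag
        )  # Im(x_i conj(x_j)) per trial
        if estimator == "pli":
            val = np.abs(np.mean(np.sign(im), axis=-1))
        elif estimator == "wpli":
            num = np.abs(np.mean(im, axis=-1))
            den = np.mean(np.abs(im), axis=-1)
            val = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        else:
            s1 = im.sum(axis=-1)
            s2 = (im**2).sum(axis=-1)
            sa = np.abs(im).sum(axis=-1)
            num = s1**2 - s2
            den = sa**2 - s2
            val = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        acc += val
    m = acc / bins.size
    m = (m + m.T) / 2.0
    np.clip(m, 0.0, None, out=m)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(m, band, estimator)
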