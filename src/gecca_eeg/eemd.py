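"""Empirical mode decomposition (EMD) and its noise-assisted ensemble (EEMD).

EMD decomposes a single signal into a small set of intrinsic mode functions
(IMFs) by *sifting*: at each step the mean of the upper and lower
cubic-spline envelopes of the local extrema is subtracted until the result
is a proper IMF — its numbers of extrema and zero crossings differ by at
most one.  Subtracting each IMF leaves a residual; the process stops when
the residual is monotone or carries fewer than two interior extrema.  By
construction the sum of all IMFs plus the residual reproduces the input.

EEMD stabilises EMD against mode mixing by averaging the decompositions of
several white-noise-perturbed copies of the signal.  Here the ensemble turns
a single contaminated EEG channel into a multichannel matrix of narrow-band
streams, the input expected by the CCA source-separation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "emd", "eemd", "reconstruct"]

_MAX_SIFTS = 50  # hard cap on sifting iterations per IMF


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residual for one channel.

    ``imfs`` is an ``(n_imfs, n_samples)`` array ordered from the fastest
    oscillation (IMF 1) to the slowest; ``residual`` is the leftover trend.
    """

    imfs: np.ndarray
    residual: np.ndarray
    source_length: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        if self.imfs.size == 0:
            self.imfs = self.imfs.reshape(0, self.source_length)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.residual.shape != (self.source_length,):
            raise ValueError("residual length does not match source_length")
        if self.imfs.shape[1] != self.source_length:
            raise ValueError("IMF length does not match source_length")

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def as_matrix(self, include_residual: bool = True) -> np.ndarray:
        """Stack IMFs (and optionally the residual) as rows of a matrix."""
        if include_residual:
            return np.vstack([self.imfs, self.residual[None, :]])
        return self.imfs.copy()


def _interior_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (plateau-tolerant)."""
    d = np.diff(x)
    s = np.sign(d)
    # forward-fill zero slopes so plateaus count once, at their far edge
    nz = s != 0
    idx = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    s = s[idx]
    turn = s[:-1] * s[1:] < 0
    pos = np.nonzero(turn)[0] + 1
    maxima = pos[s[pos - 1] > 0]
    minima = pos[s[pos - 1] < 0]
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] * s[1:] < 0))


def _is_imf(x: np.ndarray) -> bool:
    ma, mi = _interior_extrema(x)
    return abs((ma.size + mi.size) - _zero_crossings(x)) <= 1


def _envelope(t_ext: np.ndarray, v_ext: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended by 2 points.

    Mirroring the two extrema nearest each end across the signal boundary is
    the standard guard against spline overshoot at the edges.
    """
    k = min(2, t_ext.size)
    left_t = (-t_ext[:k])[::-1]
    left_v = v_ext[:k][::-1]
    right_t = (2 * (n - 1) - t_ext[-k:])[::-1]
    right_v = v_ext[-k:][::-1]
    t = np.concatenate([left_t, t_ext, right_t])
    v = np.concatenate([left_v, v_ext, right_v])
    return CubicSpline(t, v)(np.arange(n))


def emd(
    signal: np.ndarray,
    max_imfs: int = 8,
    sift_tol: float = 0.2,
) -> IMFSet:
    """Decompose ``signal`` into intrinsic mode functions by sifting.

    Parameters
    ----------
    signal
        1-D real signal, at least 8 samples, all finite.
    max_imfs
        Upper bound on the number of IMFs extracted.
    sift_tol
        Cauchy-type stopping tolerance for sifting: iteration stops once
        ``sum((h_prev - h)**2) / sum(h_prev**2) < sift_tol`` and the
        candidate satisfies the IMF extrema/zero-crossing property, or after
        50 sifts.

    Returns
    -------
    IMFSet
        IMFs ordered fast-to-slow plus the residual trend; their sum
        reproduces the input to floating-point accuracy.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 8:
        raise ValueError(f"signal too short for EMD: {x.size} < 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    n = x.size
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        ma, mi = _interior_extrema(residual)
        if ma.size < 2 or mi.size < 2:
            break  # residual is (near-)monotone: nothing left to sift
        h = residual.copy()
        for _ in range(_MAX_SIFTS):
            ma, mi = _interior_extrema(h)
            if ma.size < 2 or mi.size < 2:
                break
            mean_env = 0.5 * (
                _envelope(ma, h[ma], n) + _envelope(mi, h[mi], n)
            )
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_tol and _is_imf(h):
                break
        imfs.append(h)
        residual = residual - h

    imf_arr = np.array(imfs) if imfs else np.empty((0, n))
    return IMFSet(
        imfs=imf_arr,
        residual=residual,
        source_length=n,
        meta={"ensembles": 1, "noise_std": 0.0, "seed": None},
    )


def eemd(
    signal: np.ndarray,
    n_ensembles: int = 3,
    noise_std: float = 0.2,
    seed: int | None = None,
    max_imfs: int = 8,
    sift_tol: float = 0.2,
) -> IMFSet:
    """Ensemble EMD: average EMDs of noise-perturbed copies of ``signal``.

    Each ensemble member adds white Gaussian noise of standard deviation
    ``noise_std * std(signal)``, is EMD-decomposed, and the IMFs are
    averaged index-wise (members producing fewer IMFs contribute zeros for
    the missing slow modes).  The output is a pure function of
    ``(signal, n_ensembles, noise_std, seed)``.

    Note that only the degenerate single-member, zero-noise ensemble is an
    exact decomposition; the averaged IMFs of a true ensemble deviate from
    completeness by a residue that shrinks roughly as ``1/sqrt(n_ensembles)``.
    """
    if n_ensembles < 1:
        raise ValueError("n_ensembles must be >= 1")
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    x = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = noise_std * float(np.std(x))

    members = []
    for _ in range(n_ensembles):
        noise = sigma * rng.standard_normal(x.size)
        members.append(emd(x + noise, max_imfs=max_imfs, sift_tol=sift_tol))

    n_imf = max(m.n_imfs for m in members)
    imf_sum = np.zeros((n_imf, x.size))
    res_sum = np.zeros(x.size)
    for m in members:
        imf_sum[: m.n_imfs] += m.imfs  # zero-pad missing slow modes
        res_sum += m.residual
    return IMFSet(
        imfs=imf_sum / n_ensembles,
        residual=res_sum / n_ensembles,
        source_length=x.size,
        meta={"ensembles": n_ensembles, "noise_std": noise_std, "seed": seed},
    )


def reconstruct(imfset: IMFSet) -> np.ndarray:
    """Sum all IMFs and the residual back into a single signal."""
    if imfset.imfs.shape[1] != imfset.residual.size:
        raise ValueError("IMF / residual length mismatch")
    return imfset.imfs.sum(axis=0) + imfset.residual
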