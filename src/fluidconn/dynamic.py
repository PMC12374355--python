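"""Sliding-window circular-correlation connectivity and the fluidity statistic.

The dynamic branch of the analysis quantifies how much the instantaneous
pattern of inter-regional phase coupling reorganizes over time:

1. In sliding windows (1 s length, 0.1 s step by default) the Fisher-Lee
   circular correlation coefficient (CCor) between every pair of regional
   phase series forms one symmetric FC matrix per window:

       CCor_ij = sum_t sin(phi_i(t) - m_i) sin(phi_j(t) - m_j)
                 / sqrt( sum_t sin^2(phi_i(t) - m_i) * sum_t sin^2(phi_j(t) - m_j) )

   where ``m_i`` is the *circular* mean of phi_i within the window (the
   argument of the mean unit phasor — an arithmetic mean of wrapped angles
   would break wrap-invariance).

2. Pearson correlations between the vectorized strict upper triangles of the
   window matrices give a windows x windows recurrence ("dFC") matrix.

3. The population variance of the strict upper triangle of the dFC matrix is
   the *fluidity* — high when the network revisits distinct coupling
   configurations, near zero when connectivity is temporally rigid.

Degenerate windows (a region with zero sine-deviation energy, or an FC
pattern with zero variance across pairs, as produced by a fully phase-locked
network) are flagged and excluded from the recurrence matrix, with a log
record; Pearson correlation is undefined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signals import PhaseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "FCWindowStream",
    "DFCMatrix",
    "FluidityValue",
    "circular_correlation",
    "fc_stream",
    "dfc_matrix",
    "fluidity",
    "n_windows",
]

#: variance below this is treated as numerically zero (degenerate window)
_ZERO_VAR_TOL = 1e-20


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    length: float = 1.0
    step: float = 0.1

    def __post_init__(self):
        if not (0 < self.step <= self.length):
            raise ValueError("require 0 < step <= length")

    def in_samples(self, fs: float) -> tuple[int, int]:
        """(window length, step) in samples; fractional sizes round down."""
        length = int(self.length * fs)
        step = int(self.step * fs)
        if length < 8:
            raise ValueError("window length must span at least 8 samples")
        if step < 1:
            raise ValueError("window step must span at least 1 sample")
        return length, step


def n_windows(n_samples: int, fs: float, spec: WindowSpec) -> int:
    """Number of complete sliding windows; incomplete tail windows are dropped."""
    length, step = spec.in_samples(fs)
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


@dataclass
class FCWindowStream:
    """Ordered per-window symmetric CCor matrices (unit diagonal)."""

    matrices: np.ndarray  # (n_windows, n_regions, n_regions)
    window_starts: np.ndarray  # sample index of each window start
    window_spec: WindowSpec
    fs: float
    flagged: np.ndarray = field(default=None)  # bool per window; True = degenerate
    band: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = np.zeros(len(self.matrices), dtype=bool)

    @property
    def n_windows(self) -> int:
        return len(self.matrices)

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclass
class DFCMatrix:
    """Windows x windows recurrence matrix of FC patterns."""

    values: np.ndarray
    window_indices: np.ndarray  # indices (into the stream) of retained windows
    band: str | None = None
    subject_id: str | None = None


@dataclass(frozen=True)
class FluidityValue:
    """Variance of the dFC upper triangle; in [0, 1] by construction."""

    value: float
    band: str | None = None
    subject_id: str | None = None


def circular_correlation(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two phase series.

    Returns ``nan`` (undefined-correlation sentinel) when either series has
    zero sine-deviation energy around its circular mean (e.g. constant phase).
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1:
        raise ValueError("phase vectors must be 1-D and of equal length")
    if phase_i.size < 8:
        raise ValueError("need at least 8 samples")
    if not (np.all(np.isfinite(phase_i)) and np.all(np.isfinite(phase_j))):
        raise ValueError("phases must be finite")
    si = np.sin(phase_i - _circular_mean(phase_i))
    sj = np.sin(phase_j - _circular_mean(phase_j))
    denom = np.sqrt(np.sum(si**2) * np.sum(sj**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(si * sj) / denom)


def _circular_mean(phi: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * phi))))


def fc_stream(phases: PhaseMatrix, spec: WindowSpec | None = None) -> FCWindowStream:
    """Sliding-window CCor matrices over a multi-region phase matrix.

    Windows start at sample 0 and advance by the step; an incomplete window at
    the end is dropped. A window in which any region has zero sine-deviation
    energy is flagged (its matrix entries are computed where defined, the
    remainder set to nan) and excluded downstream.
    """
    spec = spec or WindowSpec()
    length, step = spec.in_samples(phases.fs)
    total = n_windows(phases.n_samples, phases.fs, spec)
    if total < 2:
        raise ValueError("need enough samples for at least 2 windows")
    n_reg = phases.n_regions
    starts = np.arange(total) * step

    matrices = np.empty((total, n_reg, n_reg))
    flagged = np.zeros(total, dtype=bool)
    for w, s0 in enumerate(starts):
        seg = phases.phases[:, s0 : s0 + length]
        # circular mean per region, then sine deviations
        mean = np.angle(np.mean(np.exp(1j * seg), axis=1))
        dev = np.sin(seg - mean[:, None])
        energy = np.einsum("ij,ij->i", dev, dev)
        norm = np.sqrt(energy)
        if np.any(energy == 0.0):
            flagged[w] = True
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = (dev @ dev.T) / np.outer(norm, norm)
        np.fill_diagonal(mat, 1.0)
        matrices[w] = np.clip(mat, -1.0, 1.0) if np.isfinite(mat).all() else mat
    if flagged.any():
        logger.warning(
            "flagged %d/%d degenerate windows (zero sine-deviation energy)",
            int(flagged.sum()),
            total,
        )
    return FCWindowStream(
        matrices=matrices,
        window_starts=starts,
        window_spec=spec,
        fs=phases.fs,
        flagged=flagged,
        band=phases.band,
        subject_id=phases.subject_id,
    )


def dfc_matrix(stream: FCWindowStream, exclude: np.ndarray | None = None) -> DFCMatrix:
    """Recurrence matrix: Pearson correlation of window FC patterns.

    Entry (a, b) is the Pearson correlation between the vectorized strict
    upper triangles of windows a and b. Flagged windows, windows listed in the
    optional boolean ``exclude`` mask, and windows whose upper triangle has
    (numerically) zero variance are dropped with a log record.
    """
    keep = ~stream.flagged
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    n_reg = stream.n_regions
    if n_reg < 3:
        raise ValueError("need at least 3 regions (>= 2 region pairs)")
    iu = np.triu_indices(n_reg, k=1)
    vecs = stream.matrices[:, iu[0], iu[1]]  # (n_windows, n_pairs)
    variances = vecs.var(axis=1)
    degenerate = variances <= _ZERO_VAR_TOL
    if degenerate.any():
        logger.warning(
            "excluding %d windows with zero-variance FC pattern", int(degenerate.sum())
        )
    keep &= ~degenerate
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("fewer than 2 usable windows for the dFC matrix")
    values = np.corrcoef(vecs[idx])
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return DFCMatrix(
        values=values,
        window_indices=idx,
        band=stream.band,
        subject_id=stream.subject_id,
    )


def fluidity(d: DFCMatrix) -> FluidityValue:
    """Population variance of the strict upper triangle of the dFC matrix."""
    n = d.values.shape[0]
    iu = np.triu_indices(n, k=1)
    tri = d.values[iu]
    if tri.size < 2:
        raise ValueError("need at least 2 off-diagonal dFC entries")
    return FluidityValue(
        value=float(np.var(tri)), band=d.band, subject_id=d.subject_id
    )
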