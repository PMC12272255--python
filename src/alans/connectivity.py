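"""Resting-state connectivity: per-participant correlation, Fisher group
averaging, and the correlation-to-dissimilarity transform.

The group matrix is the entrywise hyperbolic-tangent of the mean of the
inverse-hyperbolic-tangent (Fisher z) of the per-participant Pearson
matrices; averaging on the z scale is approximately variance-stabilized.
The clustering stage consumes the dissimilarity d = sqrt((1 - r) / 2),
which maps r in [-1, 1] onto d in [1, 0] and is strictly decreasing in r.
An alternative reading, d = 1 - r^2, is available behind the
``rule`` switch but is not the default (it is not monotone in r and folds
anticorrelation onto correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityStack",
    "participant_correlation",
    "stack_from_timeseries",
    "fisher_group_average",
    "correlation_to_dissimilarity",
    "bandpass_filter",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


def participant_correlation(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a (regions, timepoints) array."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-d (regions, timepoints)")
    if ts.shape[1] < 3:
        raise ValueError("need >= 3 timepoints")
    sd = ts.std(axis=1)
    if np.any(sd == 0.0):
        bad = list(np.nonzero(sd == 0.0)[0])
        raise ValueError(f"constant series (undefined correlation) at rows {bad}")
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class ConnectivityStack:
    """Per-participant symmetric Pearson matrices over a shared region set."""

    matrices: np.ndarray  # (participants, regions, regions)
    region_ids: tuple[str, ...]
    participant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must have shape (participants, regions, regions)")
        if m.shape[1] != len(self.region_ids) or m.shape[0] != len(self.participant_ids):
            raise ValueError("id lists do not match the matrix shape")
        if not np.allclose(m, np.swapaxes(m, 1, 2), atol=1e-10):
            raise ValueError("matrices must be symmetric")
        diag = m[:, np.arange(m.shape[1]), np.arange(m.shape[1])]
        if not np.allclose(diag, 1.0, atol=1e-10):
            raise ValueError("matrices must have unit diagonal")
        object.__setattr__(self, "matrices", m)

    @property
    def n_participants(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def subset(self, region_ids) -> "ConnectivityStack":
        idx = [self.region_ids.index(r) for r in region_ids]
        return ConnectivityStack(
            self.matrices[:, idx][:, :, idx], tuple(region_ids), self.participant_ids
        )


def stack_from_timeseries(
    data: np.ndarray, region_ids, participant_ids
) -> ConnectivityStack:
    """Correlate a (participants, regions, timepoints) panel participantwise."""
    data = np.asarray(data, dtype=float)
    mats = np.stack([participant_correlation(data[p]) for p in range(data.shape[0])])
    return ConnectivityStack(mats, tuple(region_ids), tuple(participant_ids))


def fisher_group_average(stack: ConnectivityStack | np.ndarray) -> np.ndarray:
    """Group correlation matrix: tanh of the mean Fisher z across participants.

    Raises on any off-diagonal |r| = 1, whose z is infinite; the offending
    (participant, region, region) triple is reported.
    """
    m = stack.matrices if isinstance(stack, ConnectivityStack) else np.asarray(stack, float)
    if m.ndim != 3:
        raise ValueError("need a (participants, regions, regions) array")
    off = ~np.eye(m.shape[1], dtype=bool)
    if np.any(np.abs(m[:, off]) >= 1.0):
        idx = np.argwhere((np.abs(m) >= 1.0) & off[None])
        p, i, j = idx[0]
        raise ValueError(
            f"|r| = 1 off-diagonal (infinite Fisher z): participant {p}, "
            f"regions ({i}, {j})"
        )
    z = np.arctanh(np.where(off[None], m, 0.0))
    group = np.tanh(z.mean(axis=0))
    np.fill_diagonal(group, 1.0)
    return group


def correlation_to_dissimilarity(r_matrix: np.ndarray, rule: str = "sqrt_half") -> np.ndarray:
    """Map a correlation matrix to a nonnegative dissimilarity with zero diagonal."""
    r = np.asarray(r_matrix, dtype=float)
    if np.any(r < -1.0) or np.any(r > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    if rule == "sqrt_half":
        d = np.sqrt((1.0 - r) / 2.0)
    elif rule == "one_minus_r_squared":
        d = 1.0 - r**2
    else:
        raise ValueError(f"unknown dissimilarity rule {rule!r}")
    np.fill_diagonal(d, 0.0)
    return d


def bandpass_filter(
    timeseries: np.ndarray, tr_seconds: float, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Zero-phase band-pass along the last axis via a frequency-domain mask.

    Keeps DFT bins with ``band[0] <= f <= band[1]`` (Hz); being an ideal
    (brick-wall) filter it is exactly zero-phase and leaves no out-of-band
    power, at the cost of mild ringing at the series edges.
    """
    ts = np.asarray(timeseries, dtype=float)
    n = ts.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(ts, axis=-1)
    return np.fft.irfft(spec * mask, n=n, axis=-1)


def write_matrix_tsv(matrix: np.ndarray, region_ids, path: str | Path) -> None:
    pd.DataFrame(matrix, index=list(region_ids), columns=list(region_ids)).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)
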