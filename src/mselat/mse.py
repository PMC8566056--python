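"""Multiscale sample entropy (MSE) of one-dimensional time series.

The statistic is Richman–Moorman sample entropy evaluated on a
coarse-grained series: at scale ``tau`` the series is averaged in
non-overlapping windows of length ``tau``, then SampEn(m, r) is the
negative log of the ratio of (m+1)-template to m-template match counts
under the Chebyshev distance, with self-matches excluded.  The tolerance
``r`` is expressed as a fraction of the *original* (pre-coarse-graining)
series' standard deviation, following the convention of the classic
multiscale-entropy literature, so that ``r`` is comparable across series
of different amplitude.

Both template sets are drawn from positions ``1..L-m`` of the
coarse-grained series (length ``L``), so every (m+1)-match is also an
m-match and the ratio A/B lies in [0, 1]; the entropy is therefore
non-negative wherever defined.  When either count is zero the entropy is
undefined; this is reported as a masked value, not an exception, since
small tolerances legitimately produce no matches on short series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MseParams",
    "EntropyMatrix",
    "ParameterError",
    "coarse_grain",
    "sample_entropy",
    "sample_entropy_counts",
    "mse_value",
    "entropy_matrix",
    "entropy_table",
]


class ParameterError(ValueError):
    """Raised when entropy parameters are invalid for the given series."""


@dataclass(frozen=True)
class MseParams:
    """Parameter triple of the multiscale entropy statistic.

    Attributes
    ----------
    m : int
        Embedding dimension (template length), ``m >= 1``.
    r : float
        Similarity factor: tolerance as a fraction of the original
        series' standard deviation, ``r > 0``.
    tau : int
        Scale factor: coarse-graining window length, ``tau >= 1``.
    """

    m: int = 1
    r: float = 0.56
    tau: int = 3

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ParameterError(f"m must be an integer >= 1, got {self.m}")
        if not self.r > 0:
            raise ParameterError(f"r must be > 0, got {self.r}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ParameterError(f"tau must be an integer >= 1, got {self.tau}")

    def validate_for_length(self, n_timepoints: int) -> None:
        """Check that a series of this length supports the parameters."""
        length = n_timepoints // self.tau
        if length - self.m < 1:
            raise ParameterError(
                f"series of length {n_timepoints} leaves only {length} "
                f"coarse-grained samples at tau={self.tau}; need at least "
                f"m+1={self.m + 1} to form templates"
            )


@dataclass
class EntropyMatrix:
    """Subjects x regions matrix of MSE values at one fixed (m, r, tau).

    ``undefined_mask`` flags entries where no template matches occurred
    (zero counts); ``values`` is NaN exactly there.
    """

    values: np.ndarray
    params: MseParams
    undefined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined_mask is None:
            self.undefined_mask = np.isnan(self.values)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.undefined_mask.shape != self.values.shape:
            raise ValueError("undefined_mask shape must match values shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_undefined(self) -> int:
        return int(self.undefined_mask.sum())


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average ``x`` in non-overlapping windows of length ``tau``.

    Returns the length ``floor(N / tau)`` series
    ``y_j = mean(x[(j-1)*tau : j*tau])``; trailing remainder samples are
    discarded.  ``tau = 1`` is the identity.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if int(tau) != tau or tau < 1 or tau > n:
        raise ParameterError(f"tau must be an integer in [1, {n}], got {tau}")
    tau = int(tau)
    length = n // tau
    if tau == 1:
        return x.copy()
    return x[: length * tau].reshape(length, tau).mean(axis=1)


# Series longer than this use a chunked pair count to bound memory at
# O(chunk * L) instead of O(L^2).
_CHUNK_THRESHOLD = 2048
_CHUNK_ROWS = 512


def sample_entropy_counts(y: np.ndarray, m: int, r_abs: float) -> tuple[int, int]:
    """Template match counts (A, B) of sample entropy.

    B counts ordered pairs (i, j), i != j, of length-``m`` templates at
    positions ``0..L-m-1`` with Chebyshev distance <= ``r_abs``; A is the
    same count for length-``m+1`` templates over the same positions.
    """
    y = np.asarray(y, dtype=float)
    length = y.size
    if int(m) != m or m < 1:
        raise ParameterError(f"m must be an integer >= 1, got {m}")
    if not r_abs > 0:
        raise ParameterError(f"r_abs must be > 0, got {r_abs}")
    n = length - m
    if n < 1:
        raise ParameterError(
            f"series of length {length} too short for m={m}: need length >= m+1"
        )
    if n <= _CHUNK_THRESHOLD:
        dist_m = np.abs(y[:n, None] - y[None, :n])
        for k in range(1, m):
            np.maximum(dist_m, np.abs(y[k : k + n, None] - y[None, k : k + n]), out=dist_m)
        b_total = int((dist_m <= r_abs).sum())
        np.maximum(dist_m, np.abs(y[m : m + n, None] - y[None, m : m + n]), out=dist_m)
        a_total = int((dist_m <= r_abs).sum())
        # diagonal (self-match) distances are zero; remove them
        return a_total - n, b_total - n
    a_total = 0
    b_total = 0
    for start in range(0, n, _CHUNK_ROWS):
        stop = min(start + _CHUNK_ROWS, n)
        dist_m = np.abs(y[start:stop, None] - y[None, :n])
        for k in range(1, m):
            np.maximum(
                dist_m,
                np.abs(y[start + k : stop + k, None] - y[None, k : k + n]),
                out=dist_m,
            )
        b_total += int((dist_m <= r_abs).sum())
        np.maximum(
            dist_m,
            np.abs(y[start + m : stop + m, None] - y[None, m : m + n]),
            out=dist_m,
        )
        a_total += int((dist_m <= r_abs).sum())
    return a_total - n, b_total - n


def sample_entropy(y: np.ndarray, m: int, r_abs: float) -> float:
    """Sample entropy ``-ln(A/B)`` of a series; NaN when undefined.

    ``r_abs`` is the absolute tolerance (already scaled by the sd of the
    original series when used inside the MSE pipeline).  Returns NaN when
    either match count is zero, mirroring the invalid-value behaviour of
    short series at small tolerances.
    """
    a_count, b_count = sample_entropy_counts(y, m, r_abs)
    if b_count == 0 or a_count == 0:
        return float("nan")
    return float(-np.log(a_count / b_count))


def mse_value(x: np.ndarray, params: MseParams) -> float:
    """MSE(tau, m, r) of a single series; NaN when undefined.

    The tolerance is ``params.r * sd(x)`` with the sd taken on the
    original series before coarse-graining.
    """
    x = np.asarray(x, dtype=float)
    params.validate_for_length(x.size)
    sd = float(np.std(x))
    if sd == 0.0:
        # constant series: every template matches every other at any r>0
        return 0.0
    y = coarse_grain(x, params.tau)
    return sample_entropy(y, params.m, params.r * sd)


def entropy_matrix(ds, params: MseParams) -> EntropyMatrix:
    """MSE of every (subject, region) series of a dataset at fixed params."""
    data = np.asarray(ds.data, dtype=float)
    params.validate_for_length(data.shape[2])
    n_subjects, n_regions = data.shape[:2]
    values = np.empty((n_subjects, n_regions), dtype=float)
    for s in range(n_subjects):
        for g in range(n_regions):
            values[s, g] = mse_value(data[s, g], params)
    return EntropyMatrix(values=values, params=params)


def _counts_at_thresholds(dist: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#entries of ``dist`` <= t for each ascending threshold t, minus the
    zero diagonal (dist must be a square template-distance matrix)."""
    idx = np.searchsorted(thresholds, dist.ravel(), side="left")
    binc = np.bincount(idx, minlength=thresholds.size + 1)
    return np.cumsum(binc)[: thresholds.size] - dist.shape[0]


def entropy_table(
    ds,
    m_values: list[int],
    r_values: list[float],
    tau_values: list[int],
) -> np.ndarray:
    """MSE over a full (m, r, tau) grid, sharing pairwise distances.

    Returns an array of shape ``[len(m_values), len(tau_values),
    len(r_values), n_subjects, n_regions]`` with NaN at undefined
    entries.  Numerically identical to looping :func:`entropy_matrix`
    over the grid (the match counts are the same integers), but far
    cheaper: the Chebyshev window distances of a series are computed once
    per (series, tau, m) and thresholded at every r at once.

    ``r_values`` must be sorted ascending; ``m_values`` may only contain
    values >= 1.
    """
    data = np.asarray(ds.data, dtype=float)
    r_values = np.asarray(r_values, dtype=float)
    if r_values.size == 0 or np.any(np.diff(r_values) < 0):
        raise ParameterError("r_values must be non-empty and sorted ascending")
    for m in m_values:
        for tau in tau_values:
            MseParams(m=m, r=float(r_values[0]), tau=tau).validate_for_length(
                data.shape[2]
            )
    n_subjects, n_regions = data.shape[:2]
    out = np.full(
        (len(m_values), len(tau_values), len(r_values), n_subjects, n_regions),
        np.nan,
    )
    max_m = max(m_values)
    for s in range(n_subjects):
        for g in range(n_regions):
            x = data[s, g]
            sd = float(np.std(x))
            if sd == 0.0:
                out[:, :, :, s, g] = 0.0
                continue
            r_abs = r_values * sd
            for ti, tau in enumerate(tau_values):
                y = coarse_grain(x, tau)
                length = y.size
                # window distance matrices: win[w] holds Chebyshev
                # distances between length-(w+1) templates
                dist = np.abs(y[:, None] - y[None, :])
                win = [dist]
                for w in range(1, max_m + 1):
                    prev = win[-1]
                    nw = length - w
                    win.append(np.maximum(prev[:nw, :nw], dist[w:, w:]))
                for mi, m in enumerate(m_values):
                    n = length - m
                    b_counts = _counts_at_thresholds(win[m - 1][:n, :n], r_abs)
                    a_counts = _counts_at_thresholds(win[m], r_abs)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        vals = -np.log(a_counts / b_counts)
                    vals[(a_counts == 0) | (b_counts == 0)] = np.nan
                    out[mi, ti, :, s, g] = vals
    return out
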