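"""Per-vertex time-series conditioning: dummy discard, DCT band-pass, z-scoring, run averaging."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct

__all__ = ["VertexTimeSeries", "dct_filter", "zscore", "preprocess_runs"]


@dataclass
class VertexTimeSeries:
    """Preprocessed series for a set of vertices.

    ``values`` is a T x V array (rows = volumes, columns = vertices); for a
    single vertex it may be a 1-D vector of length T.
    """

    values: np.ndarray
    tr: float
    n_runs_averaged: int
    condition: str | None = None
    sub_condition: str | None = None
    meta: dict = field(default_factory=dict)


def _dct_frequencies(n: int, tr: float) -> np.ndarray:
    # DCT-II basis function k has k/2 cycles over the record: f_k = k / (2 n tr)
    return np.arange(n) / (2.0 * n * tr)


def dct_filter(
    series: np.ndarray,
    tr: float,
    n_drop_low: int = 2,
    f_high: float = 0.26,
) -> np.ndarray:
    """Band-pass a series by zeroing DCT-II components.

    Removes the ``n_drop_low`` lowest-frequency non-constant components
    (slow drifts) and every component with frequency above ``f_high`` Hz.
    The constant term is kept; z-scoring removes it downstream. Operates
    along the first axis of a 1-D or 2-D array.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 8:
        raise ValueError("series too short for DCT filtering (need >= 8 samples)")
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < f_high < nyquist):
        raise ValueError(f"f_high must lie in (0, {nyquist}) Hz")
    coefs = dct(series, type=2, norm="ortho", axis=0)
    freqs = _dct_frequencies(n, tr)
    kill = np.zeros(n, dtype=bool)
    kill[1 : 1 + n_drop_low] = True
    kill[freqs > f_high] = True
    coefs[kill] = 0.0
    return idct(coefs, type=2, norm="ortho", axis=0)


def zscore(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Z-score along ``axis``; constant series raise a ValueError."""
    series = np.asarray(series, dtype=float)
    sd = series.std(axis=axis)
    if np.any(sd == 0):
        raise ValueError("constant series: z-score undefined")
    return (series - series.mean(axis=axis, keepdims=True)) / np.expand_dims(sd, axis)


def preprocess_runs(
    raw_runs: list[np.ndarray] | np.ndarray,
    design,
    condition: str | None = None,
    sub_condition: str | None = None,
) -> VertexTimeSeries:
    """Preprocess raw runs and average them.

    Per run: discard the first ``design.n_dummy`` volumes, DCT band-pass
    (:func:`dct_filter`), z-score per vertex; then average element-wise
    across runs. Runs containing a constant-valued vertex column are
    excluded from the average for that column only if the whole run is
    constant; a constant run is dropped with a warning.
    """
    runs = [np.asarray(r, dtype=float) for r in raw_runs]
    if not runs:
        raise ValueError("no runs supplied")
    lengths = {r.shape[0] for r in runs}
    if len(lengths) != 1:
        raise ValueError(f"runs of unequal length: {sorted(lengths)}")
    total = lengths.pop()
    if total != design.total_volumes:
        raise ValueError(
            f"run length {total} does not match design total volumes "
            f"{design.total_volumes}"
        )

    processed = []
    for i, run in enumerate(runs):
        active = run[design.n_dummy :]
        filtered = dct_filter(active, design.tr)
        sd = filtered.std(axis=0)
        if np.any(sd == 0):
            warnings.warn(
                f"run {i} contains constant series after filtering; run excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        processed.append(zscore(filtered))
    if not processed:
        raise ValueError("all runs excluded (constant series)")

    avg = np.mean(processed, axis=0)
    return VertexTimeSeries(
        values=avg,
        tr=design.tr,
        n_runs_averaged=len(processed),
        condition=condition if condition is not None else design.kind,
        sub_condition=sub_condition,
    )
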