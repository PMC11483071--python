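"""Exact-value Otsu thresholding.

Works on the empirical distribution of the supplied values rather than a
fixed-width histogram: candidate thresholds are the midpoints between
consecutive distinct values, and the returned threshold maximizes the
between-class variance  w0*w1*(mu0 - mu1)^2  of the split
{x <= t} / {x > t}.  Ties are broken by the lowest qualifying threshold.
This keeps the threshold well defined for float intensity data without a
binning choice, and keeps "strictly exceeds threshold" calls unambiguous.
"""

from __future__ import annotations

import numpy as np

__all__ = ["otsu_threshold"]


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance over the value sample.

    Parameters
    ----------
    values
        1D array-like of intensities with at least two distinct values.

    Raises
    ------
    ValueError
        If the input is empty or constant (degenerate histogram).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("otsu_threshold: empty input")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise ValueError("otsu_threshold: constant input has no threshold")

    n = counts.sum()
    # cumulative weight and mean of the lower class for each cut after uniq[i]
    w0 = np.cumsum(counts)[:-1]
    w1 = n - w0
    csum = np.cumsum(uniq * counts)[:-1]
    mu0 = csum / w0
    mu1 = (csum[-1] + uniq[-1] * counts[-1] - csum) / w1
    between = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    best = int(np.argmax(between))  # argmax takes the first (lowest) maximum
    return float((uniq[best] + uniq[best + 1]) / 2.0)
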