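"""Per-measurement normalizations of raw transillumination blocks.

Continuous-wave instruments report uncalibrated intensities, so only relative
variation is meaningful and each block must be rescaled before channels,
sessions, or subjects can be compared.  Four methods are supported, each using
*global* statistics pooled over all channels and frames of one block (one
subject, one side, one wavelength — never across subjects or sides):

``relative_change``
    ``x / mean(X)``
``zscore``
    ``(x - mean(X)) / std(X)``
``zero_center``
    ``x - mean(X)``
``robust``
    ``(x - median(X)) / (p75(X) - p25(X))``

Standard deviation is the population (divide-by-N) form and quantiles use
linear interpolation between order statistics (quantile ``q`` at fractional
rank ``q * (N - 1)``).  A vanishing denominator raises
:class:`~bilatdot._errors.DegenerateDataError` rather than returning zeros:
real detector data never has exactly zero spread, so hitting one indicates a
pipeline bug.
"""

from __future__ import annotations

from dataclasses import replace
from typing import NamedTuple

import numpy as np

from ._errors import DegenerateDataError, ValidationError
from .core import ScanBlock

#: Canonical token order, used for representation enumeration and concatenation.
NORMALIZATION_METHODS: tuple[str, ...] = ("relative_change", "zscore", "zero_center", "robust")


class GlobalStats(NamedTuple):
    mean: float
    std: float
    median: float
    p25: float
    p75: float


def global_stats(block: ScanBlock) -> GlobalStats:
    """Pooled statistics over all R x T entries of one block."""
    x = block.values
    return GlobalStats(
        mean=float(np.mean(x)),
        std=float(np.std(x)),  # population convention (ddof=0)
        median=float(np.median(x)),
        p25=float(np.quantile(x, 0.25)),
        p75=float(np.quantile(x, 0.75)),
    )


def normalize(block: ScanBlock, method: str) -> ScanBlock:
    """Apply one of the four global normalizations to a block.

    Parameters
    ----------
    block:
        The raw (or already transformed) intensity block.
    method:
        One of ``relative_change``, ``zscore``, ``zero_center``, ``robust``.

    Raises
    ------
    ValidationError
        On an unknown method name.
    DegenerateDataError
        When the method's denominator statistic vanishes.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValidationError(
            f"unknown normalization {method!r}; expected one of {NORMALIZATION_METHODS}"
        )
    stats = global_stats(block)
    x = block.values
    if method == "relative_change":
        if stats.mean == 0.0:
            raise DegenerateDataError("relative_change: global mean is zero")
        out = x / stats.mean
    elif method == "zscore":
        if stats.std == 0.0:
            raise DegenerateDataError("zscore: global standard deviation is zero")
        out = (x - stats.mean) / stats.std
    elif method == "zero_center":
        out = x - stats.mean
    else:  # robust
        iqr = stats.p75 - stats.p25
        if iqr == 0.0:
            raise DegenerateDataError("robust: interquartile range (p75 - p25) is zero")
        out = (x - stats.median) / iqr
    return replace(block, values=out)
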