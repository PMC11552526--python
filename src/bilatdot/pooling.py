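"""Feature calculation: raw vectorization and spatio-temporal statistical pooling.

A tumour perturbs the autonomous hemodynamics of the breast, making the
optical signal more irregular in both space and time.  The pooling operators
here turn one normalized channels x time block into a feature vector that is
sensitive to exactly that heterogeneity:

``rf``
    Raw features — the flattened matrix, channel-major (all T frames of
    channel 0, then channel 1, ...).  Length ``R * T``.
``tsd``
    Temporal standard deviation — per-channel std over time.  Length ``R``.
``ssd``
    Spatial standard deviation — per-frame std over channels.  Length ``T``.
``tf``
    Concatenation of TSD and SSD.  Length ``R + T``.
``sf``
    Six scalar heterogeneity biomarkers, see :func:`sf_metrics`.  Length 6.

All standard deviations use the population (divide-by-N) convention, matching
the normalization module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DegenerateDataError, ValidationError
from .core import ScanBlock

#: Canonical token order for enumeration and CLI/config round-trips.
POOLING_METHODS: tuple[str, ...] = ("rf", "tsd", "ssd", "tf", "sf")

#: Human-readable names of the six scalar biomarkers, in canonical order.
SF_METRIC_NAMES: tuple[str, ...] = (
    "spatial_mean_of_temporal_std",
    "spatial_std_of_temporal_std",
    "spatial_std_of_temporal_mean",
    "temporal_mean_of_spatial_std",
    "temporal_std_of_spatial_std",
    "temporal_std_of_spatial_mean",
)


@dataclass(frozen=True)
class FeatureVector:
    """A pooled feature vector with its provenance attached."""

    values: np.ndarray
    side: str
    wavelength_nm: int
    normalization: str | None
    pooling: str

    def __len__(self) -> int:
        return self.values.shape[0]


def feature_length(pooling: str, n_channels: int, n_frames: int) -> int:
    """Length contract of each pooling method for an R x T block."""
    if pooling == "rf":
        return n_channels * n_frames
    if pooling == "tsd":
        return n_channels
    if pooling == "ssd":
        return n_frames
    if pooling == "tf":
        return n_channels + n_frames
    if pooling == "sf":
        return 6
    raise ValidationError(f"unknown pooling {pooling!r}; expected one of {POOLING_METHODS}")


def _check_block(block: ScanBlock) -> None:
    if block.n_channels < 2 or block.n_frames < 2:
        raise DegenerateDataError(
            f"pooling needs R >= 2 and T >= 2, got shape {block.values.shape}"
        )


def sf_values(block: ScanBlock) -> np.ndarray:
    """The six spatio-temporal heterogeneity biomarkers of one block.

    Each biomarker composes two reductions of the channels x time matrix,
    reducing one axis and then the other with the arithmetic mean or the
    population standard deviation.  Of the eight ordered compositions, the two
    all-mean ones coincide with the global mean (uninformative after
    normalization) and are dropped, leaving six.  Canonical order::

        [ mean_s(std_t), std_s(std_t), std_s(mean_t),
          mean_t(std_s), std_t(std_s), std_t(mean_s) ]

    where ``*_t`` reduces the time axis (length-R result) and ``*_s`` reduces
    the channel axis (length-T result).  A constant block yields the zero
    vector: all six metrics are well defined (zero) there.
    """
    _check_block(block)
    x = block.values
    std_t = np.std(x, axis=1)   # length R
    mean_t = np.mean(x, axis=1)
    std_s = np.std(x, axis=0)   # length T
    mean_s = np.mean(x, axis=0)
    return np.array([
        np.mean(std_t), np.std(std_t), np.std(mean_t),
        np.mean(std_s), np.std(std_s), np.std(mean_s),
    ])


def pool_values(block: ScanBlock, method: str) -> np.ndarray:
    """Apply one pooling method, returning the bare vector."""
    if method not in POOLING_METHODS:
        raise ValidationError(f"unknown pooling {method!r}; expected one of {POOLING_METHODS}")
    _check_block(block)
    x = block.values
    if method == "rf":
        return x.ravel(order="C").copy()  # channel-major: row r contiguous
    if method == "tsd":
        return np.std(x, axis=1)
    if method == "ssd":
        return np.std(x, axis=0)
    if method == "tf":
        return np.concatenate([np.std(x, axis=1), np.std(x, axis=0)])
    return sf_values(block)


def pool(block: ScanBlock, method: str, normalization: str | None = None) -> FeatureVector:
    """Pool a block into a :class:`FeatureVector` carrying its provenance."""
    return FeatureVector(
        values=pool_values(block, method),
        side=block.side,
        wavelength_nm=block.wavelength_nm,
        normalization=normalization,
        pooling=method,
    )


def sf_metrics(block: ScanBlock, normalization: str | None = None) -> FeatureVector:
    """The six-biomarker vector as a :class:`FeatureVector` (pooling ``sf``)."""
    return FeatureVector(
        values=sf_values(block),
        side=block.side,
        wavelength_nm=block.wavelength_nm,
        normalization=normalization,
        pooling="sf",
    )
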