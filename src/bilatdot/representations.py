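"""Representation design space: enumeration, early fusion, bilateral distances.

A *representation* of one breast's data is fixed by three design choices:
which wavelengths to use ({760}, {830}, or both), which normalizations to
apply (any non-empty subset of at most three of the four methods), and one
pooling operator.  For each (wavelength, normalization) pair the pooled vector
is one *single-feature part*; the unilateral representation concatenates all
parts in canonical order (early fusion), so a single linear model can exploit
correlations between them.

Enumerating 3 wavelength choices x 14 normalization subsets (sizes 1-3 of 4)
x 5 poolings yields 210 unilateral representations.  The subset-size bounds
are parameters of :func:`enumerate_specs` so that other readings of the
design space can be explored.

The *bilateral* representation of a subject replaces each part by the
Euclidean distance between its right- and left-breast versions,
``d_l = ||X_right_l - X_left_l||``, giving one non-negative scalar per part.
This collapses the dimensionality drastically while retaining exactly the
between-breast asymmetry a unilateral tumour induces.  Distances are
accumulated part by part, so even raw-feature bilateral specs never
materialize the full concatenated unilateral vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from ._errors import ConsistencyError, ValidationError
from .core import WAVELENGTHS, SubjectRecord
from .normalization import NORMALIZATION_METHODS, normalize
from .pooling import POOLING_METHODS, FeatureVector, feature_length, pool_values

#: The three admissible wavelength selections, in canonical order.
WAVELENGTH_CHOICES: tuple[tuple[int, ...], ...] = ((760,), (830,), (760, 830))


@dataclass(frozen=True)
class RepresentationSpec:
    """One point in the pipeline's design space.

    ``wavelengths`` and ``normalizations`` are stored sorted into canonical
    order (wavelength ascending; normalizations in the fixed method order),
    so two specs denoting the same choice compare equal.
    """

    wavelengths: tuple[int, ...]
    normalizations: tuple[str, ...]
    pooling: str

    def __post_init__(self) -> None:
        wls = tuple(sorted(set(int(w) for w in self.wavelengths)))
        if not wls or any(w not in WAVELENGTHS for w in wls):
            raise ValidationError(f"wavelengths must be a non-empty subset of {WAVELENGTHS}, got {self.wavelengths}")
        norms = tuple(n for n in NORMALIZATION_METHODS if n in set(self.normalizations))
        if len(set(self.normalizations)) != len(norms) or not norms:
            unknown = set(self.normalizations) - set(NORMALIZATION_METHODS)
            raise ValidationError(
                f"normalizations must be a non-empty subset of {NORMALIZATION_METHODS}"
                + (f"; unknown: {sorted(unknown)}" if unknown else "")
            )
        if self.pooling not in POOLING_METHODS:
            raise ValidationError(f"pooling must be one of {POOLING_METHODS}, got {self.pooling!r}")
        object.__setattr__(self, "wavelengths", wls)
        object.__setattr__(self, "normalizations", norms)

    @property
    def parts(self) -> tuple[tuple[int, str], ...]:
        """Canonical (wavelength, normalization) part order: wavelength-major."""
        return tuple((w, n) for w in self.wavelengths for n in self.normalizations)

    @property
    def n_parts(self) -> int:
        return len(self.wavelengths) * len(self.normalizations)

    def unilateral_length(self, n_channels: int, n_frames: int) -> int:
        """Total concatenated feature length for an R x T block shape."""
        return self.n_parts * feature_length(self.pooling, n_channels, n_frames)

    def label(self) -> str:
        """Render the spec as its three design steps (A: wavelengths, B: normalizations, C: pooling)."""
        wl = ", ".join(f"{w} nm" for w in self.wavelengths)
        nm = " + ".join(n.replace("_", " ") for n in self.normalizations)
        return f"A: {wl}; B: {nm}; C: {self.pooling.upper()}"

    def to_dict(self) -> dict:
        return {
            "wavelengths": list(self.wavelengths),
            "normalizations": list(self.normalizations),
            "pooling": self.pooling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepresentationSpec":
        return cls(tuple(d["wavelengths"]), tuple(d["normalizations"]), d["pooling"])


@dataclass(frozen=True)
class UnilateralRepresentation:
    """Concatenated unilateral feature vector X_b with its part provenances."""

    values: np.ndarray
    side: str
    spec: RepresentationSpec
    parts: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class BilateralVector:
    """Per-part right-left Euclidean distances [d_1, ..., d_L]."""

    values: np.ndarray
    spec: RepresentationSpec


def enumerate_specs(min_normalizations: int = 1, max_normalizations: int = 3,
                    poolings: Sequence[str] = POOLING_METHODS,
                    wavelength_choices: Sequence[tuple[int, ...]] = WAVELENGTH_CHOICES,
                    ) -> list[RepresentationSpec]:
    """Enumerate the representation design space in a fixed deterministic order.

    Order is lexicographic: wavelength choice outermost (760, 830, both),
    then normalization subsets by size and position in the canonical method
    order, then pooling.  Defaults yield 3 x 14 x 5 = 210 specs.
    """
    if not 1 <= min_normalizations <= max_normalizations <= len(NORMALIZATION_METHODS):
        raise ValidationError(
            f"need 1 <= min_normalizations <= max_normalizations <= {len(NORMALIZATION_METHODS)}"
        )
    norm_subsets = [
        subset
        for size in range(min_normalizations, max_normalizations + 1)
        for subset in combinations(NORMALIZATION_METHODS, size)
    ]
    return [
        RepresentationSpec(wls, norms, pooling)
        for wls in wavelength_choices
        for norms in norm_subsets
        for pooling in poolings
    ]


def single_feature_specs(poolings: Sequence[str] = POOLING_METHODS,
                         wavelength_choices: Sequence[tuple[int, ...]] = ((760,), (830,)),
                         ) -> list[RepresentationSpec]:
    """Specs with one wavelength and one normalization — the L=1 representations."""
    return [
        RepresentationSpec(wls, (norm,), pooling)
        for wls in wavelength_choices
        for norm in NORMALIZATION_METHODS
        for pooling in poolings
    ]


def iter_part_vectors(record: SubjectRecord, side: str, spec: RepresentationSpec,
                      ) -> Iterable[tuple[tuple[int, str], np.ndarray]]:
    """Yield ((wavelength, normalization), pooled vector) per part, in canonical order."""
    for wl, norm in spec.parts:
        block = record.block(side, wl)
        try:
            yield (wl, norm), pool_values(normalize(block, norm), spec.pooling)
        except Exception as exc:
            exc.add_note(
                f"while building part (wavelength={wl}, normalization={norm}) "
                f"of {record.subject_id!r}/{side}"
            )
            raise


def build_unilateral(record: SubjectRecord, side: str, spec: RepresentationSpec,
                     ) -> UnilateralRepresentation:
    """Concatenate all single-feature parts of one breast into X_b."""
    parts: list[tuple[int, str]] = []
    vectors: list[np.ndarray] = []
    for key, vec in iter_part_vectors(record, side, spec):
        parts.append(key)
        vectors.append(vec)
    return UnilateralRepresentation(
        values=np.concatenate(vectors), side=side, spec=spec, parts=tuple(parts),
    )


def build_bilateral(record: SubjectRecord, spec: RepresentationSpec) -> BilateralVector:
    """Per-part Euclidean distances between the right and left breast features.

    Parts are streamed: each part's right and left vectors are built, their
    distance taken, and the vectors discarded, so memory stays proportional
    to one block even for raw-feature specs.
    """
    distances = []
    left_iter = iter_part_vectors(record, "left", spec)
    right_iter = iter_part_vectors(record, "right", spec)
    for (key_r, vec_r), (key_l, vec_l) in zip(right_iter, left_iter):
        if vec_r.shape != vec_l.shape:
            raise ConsistencyError(
                f"{record.subject_id!r} part {key_r}: side dimension mismatch "
                f"{vec_r.shape} vs {vec_l.shape}"
            )
        distances.append(float(np.linalg.norm(vec_r - vec_l)))
    return BilateralVector(values=np.array(distances), spec=spec)
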