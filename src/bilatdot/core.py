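"""Core data model for bilateral diffuse-optical transillumination time series.

A continuous-wave optical mammography instrument transilluminates both
breasts simultaneously through a fibre-optic interface carrying ``n_sources``
emitters and ``n_detectors`` detectors per side, at two near-infrared
wavelengths (760 and 830 nm).  Every source-detector pair is one *channel*;
a measurement is a channels x time matrix of detector voltages in arbitrary
(uncalibrated) units.  The types here hold one such matrix (:class:`ScanBlock`),
the four matrices of one subject (:class:`SubjectRecord`), and a study cohort
(:class:`Cohort`), together with the preprocessing that is applied before any
feature computation: truncation to a fixed-length resting phase and channel
subsetting for sparse-array emulation.

Conventions fixed here and relied on everywhere else:

* indexing is 0-based with half-open ranges;
* channels are ordered **source-major**: channel ``r = source * n_detectors +
  detector``, so the detector index varies fastest;
* standard deviations downstream use the population (divide-by-N) convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Mapping

import numpy as np

from ._errors import (
    ConsistencyError,
    FormatError,
    InsufficientDataError,
    RangeError,
    ValidationError,
)

Side = Literal["left", "right"]
WAVELENGTHS: tuple[int, int] = (760, 830)
SIDES: tuple[Side, Side] = ("left", "right")

MANIFEST_NAME = "manifest.json"
MANIFEST_SCHEMA_VERSION = 1


def channel_index(source: int, detector: int, n_detectors: int, n_sources: int = 32) -> int:
    """Map a (source, detector) pair to its flat channel index.

    The mapping is ``source * n_detectors + detector`` — source-major, a
    bijection onto ``[0, n_sources * n_detectors)``.

    Raises
    ------
    RangeError
        If either index is outside its axis.
    """
    if not 0 <= source < n_sources:
        raise RangeError(f"source index {source} out of range [0, {n_sources})")
    if not 0 <= detector < n_detectors:
        raise RangeError(f"detector index {detector} out of range [0, {n_detectors})")
    return source * n_detectors + detector


@dataclass(frozen=True)
class ScanBlock:
    """One channels x time intensity matrix for a (subject, side, wavelength).

    ``values`` has shape ``(R, T)`` with ``R = n_sources * n_detectors``
    channels ordered source-major.  Raw blocks are strictly positive detector
    voltages; normalized blocks may hold any finite real values.
    """

    values: np.ndarray
    wavelength_nm: int
    side: Side
    n_sources: int = 32
    n_detectors: int = 64

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D (channels x time), got ndim={values.ndim}")
        if self.n_sources < 1 or self.n_detectors < 1:
            raise ValidationError("n_sources and n_detectors must be positive")
        r_expected = self.n_sources * self.n_detectors
        if values.shape[0] != r_expected:
            raise ValidationError(
                f"channel axis has {values.shape[0]} rows, expected "
                f"n_sources*n_detectors={r_expected}"
            )
        if values.shape[1] < 1:
            raise ValidationError("time axis must have at least one frame")
        if self.wavelength_nm not in WAVELENGTHS:
            raise ValidationError(f"wavelength_nm must be one of {WAVELENGTHS}, got {self.wavelength_nm}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubjectRecord:
    """The four scan blocks of one subject plus diagnosis and laterality.

    ``blocks`` maps ``(side, wavelength_nm)`` to a :class:`ScanBlock`; exactly
    the four combinations of {left, right} x {760, 830} must be present and
    share one shape.  ``tumor_side`` is ``"none"`` for cancer-negative
    subjects; bilateral symmetric cancer is not modelled.
    """

    subject_id: str
    blocks: Mapping[tuple[Side, int], ScanBlock]
    cancer_positive: bool
    tumor_side: Literal["left", "right", "none"] = "none"

    def __post_init__(self) -> None:
        expected = {(s, w) for s in SIDES for w in WAVELENGTHS}
        got = set(self.blocks.keys())
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValidationError(
                f"record {self.subject_id!r} must have exactly 4 blocks; "
                f"missing={missing}, unexpected={extra}"
            )
        shapes = {b.values.shape for b in self.blocks.values()}
        if len(shapes) != 1:
            raise ConsistencyError(
                f"record {self.subject_id!r}: all blocks must share one shape, got {sorted(shapes)}"
            )
        if self.cancer_positive != (self.tumor_side != "none"):
            raise ValidationError(
                f"record {self.subject_id!r}: cancer_positive={self.cancer_positive} "
                f"inconsistent with tumor_side={self.tumor_side!r}"
            )

    def block(self, side: Side, wavelength_nm: int) -> ScanBlock:
        return self.blocks[(side, wavelength_nm)]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.blocks.values())).values.shape


@dataclass(frozen=True)
class Cohort:
    """An ordered list of subject records sharing block dimensions."""

    records: tuple[SubjectRecord, ...]
    frame_rate_hz: float = 1.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids must be unique")
        shapes = {r.shape for r in self.records}
        if len(shapes) > 1:
            raise ConsistencyError(f"all records must share block dimensions, got {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.cancer_positive for r in self.records)


@dataclass(frozen=True)
class GridGeometry:
    """A subset of source and detector positions emulating a sparser array."""

    kept_sources: tuple[int, ...]
    kept_detectors: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kept_sources", tuple(int(i) for i in self.kept_sources))
        object.__setattr__(self, "kept_detectors", tuple(int(i) for i in self.kept_detectors))
        for label, idx in (("kept_sources", self.kept_sources), ("kept_detectors", self.kept_detectors)):
            if len(idx) == 0:
                raise ValidationError(f"{label} must be non-empty")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValidationError(f"{label} must be strictly increasing, got {idx}")
            if idx[0] < 0:
                raise RangeError(f"{label} contains negative index {idx[0]}")

    @property
    def size_label(self) -> str:
        return f"{len(self.kept_sources)}x{len(self.kept_detectors)}"


def full_grid(n_sources: int = 32, n_detectors: int = 64) -> GridGeometry:
    """The identity geometry keeping every source and detector."""
    return GridGeometry(tuple(range(n_sources)), tuple(range(n_detectors)), name=f"full_{n_sources}x{n_detectors}")


def evenly_spaced_grid(n_keep_sources: int, n_keep_detectors: int,
                       n_sources: int = 32, n_detectors: int = 64,
                       offset_sources: int = 0, offset_detectors: int = 0,
                       name: str | None = None) -> GridGeometry:
    """A maximally even subset of the full optode grid.

    Picks ``n_keep`` indices spread uniformly over each axis (rounded to the
    nearest available position), emulating the homogeneous spatial coverage a
    sparser instrument would be designed with.  ``offset_*`` shifts the comb to
    produce distinct arrangements of the same size.
    """
    def pick(n_keep: int, n_total: int, offset: int) -> tuple[int, ...]:
        if n_keep > n_total:
            raise ValidationError(f"cannot keep {n_keep} of {n_total} positions")
        idx = (np.floor(np.arange(n_keep) * n_total / n_keep).astype(int) + offset) % n_total
        return tuple(sorted(int(i) for i in idx))

    label = name or f"even_{n_keep_sources}x{n_keep_detectors}_o{offset_sources}{offset_detectors}"
    return GridGeometry(pick(n_keep_sources, n_sources, offset_sources),
                        pick(n_keep_detectors, n_detectors, offset_detectors), name=label)


def truncate_rest_phase(block: ScanBlock, n_frames: int) -> ScanBlock:
    """Keep the first ``n_frames`` time frames of a block.

    Imaging sessions start with a resting period of varying length; all
    analyses use a fixed-length leading segment so feature vectors are
    commensurate across subjects.

    Raises
    ------
    InsufficientDataError
        If the block has fewer than ``n_frames`` frames.
    """
    if n_frames < 1:
        raise ValidationError(f"n_frames must be >= 1, got {n_frames}")
    if block.n_frames < n_frames:
        raise InsufficientDataError(
            f"block has T={block.n_frames} frames, cannot truncate to n_frames={n_frames}"
        )
    if block.n_frames == n_frames:
        return block
    return replace(block, values=block.values[:, :n_frames].copy())


def subset_channels(block: ScanBlock, grid: GridGeometry) -> ScanBlock:
    """Restrict a block to the channels formed by a sparse optode geometry.

    The output keeps rows ``{channel_index(s, d) : s in kept_sources,
    d in kept_detectors}`` ordered source-major by the kept lists, so the
    result is itself a valid source-major block with ``|kept_sources|``
    sources and ``|kept_detectors|`` detectors.
    """
    if grid.kept_sources[-1] >= block.n_sources:
        raise RangeError(
            f"grid {grid.name!r}: source index {grid.kept_sources[-1]} out of range "
            f"[0, {block.n_sources})"
        )
    if grid.kept_detectors[-1] >= block.n_detectors:
        raise RangeError(
            f"grid {grid.name!r}: detector index {grid.kept_detectors[-1]} out of range "
            f"[0, {block.n_detectors})"
        )
    src = np.asarray(grid.kept_sources)
    det = np.asarray(grid.kept_detectors)
    rows = (src[:, None] * block.n_detectors + det[None, :]).ravel()
    return ScanBlock(
        values=block.values[rows, :].copy(),
        wavelength_nm=block.wavelength_nm,
        side=block.side,
        n_sources=len(src),
        n_detectors=len(det),
    )


def subset_cohort(cohort: Cohort, grid: GridGeometry) -> Cohort:
    """Apply :func:`subset_channels` to every block of every record."""
    records = []
    for rec in cohort:
        blocks = {key: subset_channels(b, grid) for key, b in rec.blocks.items()}
        records.append(replace(rec, blocks=blocks))
    return Cohort(tuple(records), frame_rate_hz=cohort.frame_rate_hz)


# ---------------------------------------------------------------------------
# On-disk cohort container
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, path: str | Path, fmt: Literal["npy", "csv"] = "npy",
                extra_manifest: Mapping[str, object] | None = None) -> Path:
    """Write a cohort to a directory container.

    Layout: ``manifest.json`` plus one matrix file per (subject, side,
    wavelength) named ``<subject_id>_<side>_<wavelength>.npy`` (or ``.csv``),
    rows = channels (source-major), columns = time frames.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    first = cohort.records[0] if cohort.records else None
    manifest: dict[str, object] = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "format": fmt,
        "frame_rate_hz": cohort.frame_rate_hz,
        "n_sources": first.blocks[("left", 760)].n_sources if first else 0,
        "n_detectors": first.blocks[("left", 760)].n_detectors if first else 0,
        "n_frames": first.shape[1] if first else 0,
        "subjects": [
            {
                "subject_id": r.subject_id,
                "cancer_positive": r.cancer_positive,
                "tumor_side": r.tumor_side,
            }
            for r in cohort.records
        ],
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    for rec in cohort:
        for (side, wl), block in rec.blocks.items():
            stem = f"{rec.subject_id}_{side}_{wl}"
            if fmt == "npy":
                np.save(path / f"{stem}.npy", block.values)
            elif fmt == "csv":
                np.savetxt(path / f"{stem}.csv", block.values, delimiter=",")
            else:
                raise ValidationError(f"unknown container format {fmt!r}")
    return path


def load_cohort(path: str | Path) -> Cohort:
    """Load a cohort container written by :func:`save_cohort`.

    Raises
    ------
    FormatError
        On a missing manifest, a missing block file, or a matrix whose shape
        disagrees with the manifest.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FormatError(f"missing manifest: {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable manifest {manifest_path}: {exc}") from exc
    for field_name in ("n_sources", "n_detectors", "n_frames", "frame_rate_hz", "subjects", "format"):
        if field_name not in manifest:
            raise FormatError(f"manifest {manifest_path} missing field {field_name!r}")
    n_sources = int(manifest["n_sources"])
    n_detectors = int(manifest["n_detectors"])
    n_frames = int(manifest["n_frames"])
    fmt = manifest["format"]
    records = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        blocks: dict[tuple[Side, int], ScanBlock] = {}
        for side in SIDES:
            for wl in WAVELENGTHS:
                stem = path / f"{sid}_{side}_{wl}"
                if fmt == "npy":
                    file = stem.with_suffix(".npy")
                    if not file.is_file():
                        raise FormatError(f"missing block file for key ({side}, {wl}): {file}")
                    values = np.load(file)
                elif fmt == "csv":
                    file = stem.with_suffix(".csv")
                    if not file.is_file():
                        raise FormatError(f"missing block file for key ({side}, {wl}): {file}")
                    values = np.loadtxt(file, delimiter=",", ndmin=2)
                else:
                    raise FormatError(f"manifest declares unknown format {fmt!r}")
                if values.shape != (n_sources * n_detectors, n_frames):
                    raise FormatError(
                        f"{file}: matrix shape {values.shape} disagrees with manifest "
                        f"({n_sources * n_detectors}, {n_frames})"
                    )
                blocks[(side, wl)] = ScanBlock(
                    values=values, wavelength_nm=wl, side=side,
                    n_sources=n_sources, n_detectors=n_detectors,
                )
        records.append(SubjectRecord(
            subject_id=sid,
            blocks=blocks,
            cancer_positive=bool(entry["cancer_positive"]),
            tumor_side=entry["tumor_side"],
        ))
    return Cohort(tuple(records), frame_rate_hz=float(manifest["frame_rate_hz"]))


def load_osf_deposition(path: str | Path) -> Cohort:  # pragma: no cover - adapter stub
    """Adapter stub for the public OSF deposition of the clinical study data.

    The deposited files must first be converted into the directory container
    documented in :func:`save_cohort`; this function is the intended hook for
    that conversion.  It is not implemented because the deposition's native
    layout is only discoverable from the deposition itself, and no analysis in
    this package requires the clinical data.
    """
    raise NotImplementedError(
        "Download the deposition, convert it to the cohort container layout "
        "(manifest.json + one matrix per subject/side/wavelength), then use load_cohort()."
    )
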