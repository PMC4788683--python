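"""Sequences, residue-level domain/linker annotations, and domain segments.

Residue coordinates are 1-based inclusive everywhere in files, messages and the
public API (the convention of CATH-style segment definitions). A per-residue
annotation is a string over ``{D, L, U}``: D marks a domain residue, L a linker
(non-domain) residue, and U an unpredicted position — U never appears in ground
truth, only in prediction output where the sliding window does not fit.

In the ±k boundary-relaxation mode the positive class is inverted: every
residue within k positions of a linker region is treated as a boundary
positive. :func:`boundary_annotation` emits those positives as D so that the
downstream machinery (which always treats D as positive) is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlphabetError,
    DuplicateIdError,
    EmptyDatasetError,
    FormatError,
    LengthMismatchError,
    RangeError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted ambiguity/nonstandard codes (imputed with scale means downstream).
AMBIGUITY_CODES = "XBZU"
ALPHABET = frozenset(STANDARD_AA + AMBIGUITY_CODES)

LABEL_DOMAIN = "D"
LABEL_LINKER = "L"
LABEL_UNKNOWN = "U"
_LABELS = frozenset("DLU")


class PositiveClass(str, Enum):
    """Which residue class counts as positive during training/evaluation."""

    DOMAIN = "domain"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an upper-case amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise AlphabetError(
                    f"protein {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-residue labels over {D, L, U}, paired with a sequence of equal length."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - _LABELS
        if bad:
            raise FormatError(
                f"annotation contains characters outside {{D,L,U}}: {sorted(bad)}"
            )
        if not self.labels:
            raise FormatError("empty annotation")

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return self.labels.count(label)

    def positive_mask(self) -> np.ndarray:
        """Boolean mask of D positions."""
        return np.frombuffer(self.labels.encode(), dtype="S1") == b"D"


@dataclass(frozen=True)
class DomainDefinition:
    """Sorted, merged 1-based inclusive domain segments.

    Overlapping and exactly-adjacent segments (``end_i + 1 == start_{i+1}``)
    are merged silently at construction.
    """

    segments: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for start, end in sorted(self.segments):
            if start < 1 or end < start:
                raise RangeError(f"invalid segment ({start}, {end})")
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "segments", tuple(merged))

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class BoundaryConfig:
    """Evaluation convention: residue margin k and which class is positive.

    ``k=0`` with ``positive_class=DOMAIN`` is the strict domain/linker
    convention; ``k=20`` with ``positive_class=BOUNDARY`` is the relaxed
    boundary-prediction convention used for cross-method comparison.
    """

    k: int = 0
    positive_class: PositiveClass = PositiveClass.DOMAIN

    def __post_init__(self) -> None:
        from .errors import ConfigError

        if self.k < 0:
            raise ConfigError(f"boundary margin k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder values in [0, 1] (1 = disordered)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        for i, v in enumerate(vals, start=1):
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise FormatError(f"disorder value out of [0,1] at position {i}: {v}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# segment <-> residue conversions


def annotation_from_domains(domains: DomainDefinition, length: int) -> ResidueAnnotation:
    """Label position i D iff it lies in some domain segment, else L."""
    labels = np.full(length, LABEL_LINKER, dtype="U1")
    for start, end in domains:
        if start < 1 or end > length:
            raise RangeError(
                f"segment ({start}, {end}) outside sequence of length {length}"
            )
        labels[start - 1 : end] = LABEL_DOMAIN
    return ResidueAnnotation("".join(labels))


def segments_from_annotation(annotation: ResidueAnnotation) -> DomainDefinition:
    """Maximal runs of D as a segment list (inverse of annotation_from_domains)."""
    if LABEL_UNKNOWN in annotation.labels:
        raise FormatError("cannot extract segments from an annotation containing U")
    segments: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(annotation.labels, start=1):
        if ch == LABEL_DOMAIN and start is None:
            start = i
        elif ch != LABEL_DOMAIN and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(annotation)))
    return DomainDefinition(tuple(segments))


def boundary_annotation(
    domains: DomainDefinition, length: int, k: int
) -> ResidueAnnotation:
    """Relaxed boundary labels: positive (D) within k residues of any linker.

    With k=0 the positive set is exactly the complement of the domain residues.
    k-expansion applies to all linker segments including chain-terminal ones.
    """
    if k < 0:
        from .errors import ConfigError

        raise ConfigError(f"k must be >= 0, got {k}")
    base = annotation_from_domains(domains, length)
    linker = ~base.positive_mask()
    if k > 0 and linker.any():
        positions = np.arange(length)
        dist = np.min(
            np.abs(positions[:, None] - positions[linker][None, :]), axis=1
        )
        positive = dist <= k
    else:
        positive = linker
    labels = np.where(positive, LABEL_DOMAIN, LABEL_LINKER)
    return ResidueAnnotation("".join(labels))


def relabel_boundary(annotation: ResidueAnnotation, k: int) -> ResidueAnnotation:
    """Convert a strict D/L ground truth into ±k boundary-positive labels."""
    domains = segments_from_annotation(annotation)
    return boundary_annotation(domains, len(annotation), k)


# ---------------------------------------------------------------------------
# file I/O


def parse_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated, uppercased protein records."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise EmptyDatasetError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_annotations(
    path: str | Path, sequences: Mapping[str, ProteinRecord] | None = None
) -> dict[str, ResidueAnnotation]:
    """Read a two-column TSV (id TAB D/L/U string)."""
    out: dict[str, ResidueAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pid, labels = parts
            if pid in out:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate id {pid!r}")
            try:
                out[pid] = ResidueAnnotation(labels)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if sequences is not None:
        for pid, ann in out.items():
            if pid in sequences and len(ann) != sequences[pid].length:
                raise LengthMismatchError(
                    f"annotation for {pid!r} has length {len(ann)}, "
                    f"sequence has length {sequences[pid].length}"
                )
    return out


def write_annotations(annotations: Mapping[str, ResidueAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in annotations:
            fh.write(f"{pid}\t{annotations[pid].labels}\n")


def read_disorder(
    path: str | Path, sequences: Mapping[str, ProteinRecord] | None = None
) -> dict[str, DisorderTrack]:
    """Read disorder tracks: id TAB (comma-separated floats | 0/1 string)."""
    out: dict[str, DisorderTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pid, payload = parts
            if pid in out:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate id {pid!r}")
            try:
                if "," in payload:
                    values = tuple(float(v) for v in payload.split(","))
                elif set(payload) <= {"0", "1"}:
                    values = tuple(float(c) for c in payload)
                else:
                    raise FormatError(
                        "payload is neither a 0/1 string nor comma-separated floats"
                    )
                out[pid] = DisorderTrack(values)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if sequences is not None:
        for pid, track in out.items():
            if pid in sequences and len(track) != sequences[pid].length:
                raise LengthMismatchError(
                    f"disorder track for {pid!r} has length {len(track)}, "
                    f"sequence has length {sequences[pid].length}"
                )
    return out


def write_disorder(tracks: Mapping[str, DisorderTrack], path: str | Path) -> None:
    """Write tracks; binary tracks compactly as 0/1 strings, else comma floats."""
    with open(path, "w") as fh:
        for pid, track in tracks.items():
            vals = track.values
            if all(v in (0.0, 1.0) for v in vals):
                payload = "".join(str(int(v)) for v in vals)
            else:
                payload = ",".join(format(v, ".6g") for v in vals)
            fh.write(f"{pid}\t{payload}\n")


def read_segments(path: str | Path) -> dict[str, DomainDefinition]:
    """Read a three-column TSV (id, start, end; one segment per line)."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            pid, start_s, end_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            raw.setdefault(pid, []).append((start, end))
    return {pid: DomainDefinition(tuple(segs)) for pid, segs in raw.items()}


def write_segments(definitions: Mapping[str, DomainDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, domains in definitions.items():
            for start, end in domains:
                fh.write(f"{pid}\t{start}\t{end}\n")
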