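"""Feature encoding: linker index derivation and sliding-window samples.

Each residue is described by F channels — four physicochemical scales plus,
optionally, a predicted-disorder value — and a classification instance is the
concatenation of those channels over a w-residue window centred on the residue
being classified (default w = 17). Residues closer than (w-1)/2 to either
terminus never sit at a window centre and are excluded from the decision
process.

The DomCut-style linker index is

    S_i = -ln(f_i_linker / f_i_domain)

where the f's are pseudocounted frequencies of residue i in linker and domain
regions of an annotated corpus; S_i < 0 means residue i is more likely to be
found in a linker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .annotations import (
    LABEL_DOMAIN,
    LABEL_LINKER,
    STANDARD_AA,
    DisorderTrack,
    ProteinRecord,
    ResidueAnnotation,
)
from .errors import ConfigError, FormatError, LengthMismatchError, MissingChannelError
from .scales import DEFAULT_SCALES, AAScale

logger = logging.getLogger(__name__)

#: Name of the disorder channel in channel manifests.
DISORDER_CHANNEL = "disorder"


@dataclass(frozen=True)
class LinkerFrequencies:
    """Pseudocounted residue frequencies in linker and domain regions."""

    f_linker: Mapping[str, float]
    f_domain: Mapping[str, float]
    pseudocount: float

    def __post_init__(self) -> None:
        for name, freqs in (("f_linker", self.f_linker), ("f_domain", self.f_domain)):
            if set(freqs) != set(STANDARD_AA):
                raise FormatError(f"{name}: expected the 20 standard residues")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise FormatError(f"{name}: frequencies sum to {total}, not 1")
            if any(v <= 0 for v in freqs.values()):
                raise FormatError(f"{name}: zero frequency after pseudocounting")


def linker_frequencies(
    proteins: Sequence[ProteinRecord],
    annotations: Mapping[str, ResidueAnnotation],
    pseudocount: float = 1.0,
) -> LinkerFrequencies:
    """Count D- and L-region residue frequencies over an annotated corpus.

    Ambiguity codes are skipped; the pseudocount is added once per residue
    type per class (Laplace smoothing), so no frequency is ever zero unless
    pseudocount=0 and a class is empty.
    """
    counts = {LABEL_LINKER: dict.fromkeys(STANDARD_AA, 0), LABEL_DOMAIN: dict.fromkeys(STANDARD_AA, 0)}
    for protein in proteins:
        ann = annotations[protein.id]
        if len(ann) != protein.length:
            raise LengthMismatchError(
                f"annotation for {protein.id!r} has length {len(ann)}, "
                f"sequence has length {protein.length}"
            )
        for aa, label in zip(protein.sequence, ann.labels):
            if label in counts and aa in counts[label]:
                counts[label][aa] += 1
    out = {}
    for label, table in counts.items():
        total = sum(table.values()) + 20 * pseudocount
        if total <= 0:
            raise ConfigError(
                f"no {'linker' if label == LABEL_LINKER else 'domain'} residues in "
                "corpus and pseudocount is 0: frequencies undefined"
            )
        out[label] = {aa: (c + pseudocount) / total for aa, c in table.items()}
    return LinkerFrequencies(
        f_linker=out[LABEL_LINKER], f_domain=out[LABEL_DOMAIN], pseudocount=pseudocount
    )


def derive_linker_index(
    proteins: Sequence[ProteinRecord],
    annotations: Mapping[str, ResidueAnnotation],
    pseudocount: float = 1.0,
) -> AAScale:
    """Compute S_i = -ln(f_linker/f_domain) from an annotated corpus."""
    freqs = linker_frequencies(proteins, annotations, pseudocount)
    values = {
        aa: -math.log(freqs.f_linker[aa] / freqs.f_domain[aa]) for aa in STANDARD_AA
    }
    return AAScale("DERIVED", values)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry and enabled feature channels.

    Scales are min–max normalized onto [0, 1] at encoding time so the
    channels are commensurate (disorder values already live in [0, 1]).
    """

    width: int = 17
    scales: tuple[AAScale, ...] = DEFAULT_SCALES
    use_disorder: bool = True

    def __post_init__(self) -> None:
        if self.width < 3 or self.width % 2 == 0:
            raise ConfigError(f"window width must be odd and >= 3, got {self.width}")
        object.__setattr__(self, "scales", tuple(self.scales))

    @property
    def half(self) -> int:
        return (self.width - 1) // 2

    @property
    def n_channels(self) -> int:
        return len(self.scales) + (1 if self.use_disorder else 0)

    @property
    def channels(self) -> tuple[str, ...]:
        names = tuple(s.accession for s in self.scales)
        return names + ((DISORDER_CHANNEL,) if self.use_disorder else names[:0])

    @property
    def n_features(self) -> int:
        return self.width * self.n_channels


@dataclass(frozen=True)
class WindowSample:
    """One classification instance: the w x F vector for one window centre."""

    protein_id: str
    center: int  # 1-based residue position
    label: bool | None  # positive / negative, None when no annotation given
    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))


def _channel_matrix(
    protein: ProteinRecord, cfg: WindowConfig, disorder: DisorderTrack | None
) -> np.ndarray:
    """Per-residue channel values, shape (L, F)."""
    columns = []
    for scale in cfg.scales:
        norm = scale.normalized()
        table = {aa: norm.values[aa] for aa in norm.values}
        mean = norm.mean
        columns.append(
            np.array([table.get(ch, mean) for ch in protein.sequence], dtype=float)
        )
    if cfg.use_disorder:
        if disorder is None:
            raise MissingChannelError(
                f"protein {protein.id!r}: disorder channel enabled but no track given"
            )
        if len(disorder) != protein.length:
            raise LengthMismatchError(
                f"protein {protein.id!r}: disorder track length {len(disorder)} "
                f"!= sequence length {protein.length}"
            )
        columns.append(disorder.as_array())
    return np.column_stack(columns)


def encode_matrix(
    protein: ProteinRecord,
    cfg: WindowConfig,
    disorder: DisorderTrack | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode all full windows of a protein.

    Returns ``(X, centers)`` where X has shape (max(0, L-w+1), w*F) with
    residue-major ordering (all F channel values of window position 1, then
    position 2, ...) and ``centers`` holds the matching 1-based centre
    positions, running from (w+1)/2 to L-(w-1)/2.
    """
    w = cfg.width
    n = protein.length - w + 1
    if n <= 0:
        logger.warning(
            "protein %s: length %d < window width %d, no windows encoded",
            protein.id, protein.length, w,
        )
        return np.empty((0, cfg.n_features)), np.empty(0, dtype=int)
    channels = _channel_matrix(protein, cfg, disorder)
    windows = sliding_window_view(channels, w, axis=0)  # (n, F, w)
    X = np.ascontiguousarray(windows.transpose(0, 2, 1)).reshape(n, w * cfg.n_channels)
    centers = np.arange(cfg.half + 1, protein.length - cfg.half + 1)
    return X, centers


def encode_windows(
    protein: ProteinRecord,
    cfg: WindowConfig,
    disorder: DisorderTrack | None = None,
    annotation: ResidueAnnotation | None = None,
) -> list[WindowSample]:
    """Encode a protein into labelled window samples.

    When an annotation is supplied, the label is True iff the central residue
    is a domain (D) residue — the positive class of the main convention. For
    the boundary-relaxed mode, relabel the annotation first.
    """
    X, centers = encode_matrix(protein, cfg, disorder)
    if annotation is not None and len(annotation) != protein.length:
        raise LengthMismatchError(
            f"protein {protein.id!r}: annotation length {len(annotation)} "
            f"!= sequence length {protein.length}"
        )
    samples = []
    for row, center in zip(X, centers):
        label = None
        if annotation is not None:
            label = annotation.labels[center - 1] == LABEL_DOMAIN
        samples.append(
            WindowSample(protein_id=protein.id, center=int(center), label=label, vector=row)
        )
    return samples
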