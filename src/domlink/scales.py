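"""Amino-acid property scales.

An :class:`AAScale` maps each of the 20 standard residues to a real number.
Four scales from the AAindex database (release 9.0) are vendored as constant
tables, chosen for their relevance to domain architecture:

- ``VINM940101`` — normalized average flexibility parameter (B-value);
  multidomain proteins are more flexible, especially around linkers.
- ``GRAR740102`` — polarity; the polar/nonpolar side-chain distribution drives
  the hydrophobic-core packing that defines a domain.
- ``JURD980101`` — modified Kyte–Doolittle hydrophobicity; linkers are more
  solvent-exposed and hydrophilic than domain cores.
- ``BAEK050101`` — linker propensity index derived from amino-acid composition
  of inter-domain linkers in nonredundant structure sets.

A reader for the AAindex flat-file format is provided so any of the 544
catalogue entries can be substituted. Scales derived from an annotated corpus
(the DomCut-style linker index ``S_i``) carry the accession ``"DERIVED"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .annotations import AMBIGUITY_CODES, STANDARD_AA
from .errors import AlphabetError, FormatError


@dataclass(frozen=True)
class AAScale:
    """A 20-entry residue -> value lookup with an AAindex-style accession."""

    accession: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            raise FormatError(
                f"scale {self.accession}: expected exactly the 20 standard residues, "
                f"got {len(keys)} keys"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise FormatError(f"scale {self.accession}: non-finite value for {aa}")
        object.__setattr__(self, "values", dict(self.values))

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / 20.0

    def lookup(self, residue: str) -> float:
        """Scale value for a residue; ambiguity codes get the 20-value mean."""
        if residue in self.values:
            return self.values[residue]
        if residue in AMBIGUITY_CODES:
            return self.mean
        raise AlphabetError(f"unknown residue {residue!r} for scale {self.accession}")

    def normalized(self) -> "AAScale":
        """Affine min–max rescaling onto [0, 1]; a constant scale maps to 0.5."""
        lo = min(self.values.values())
        hi = max(self.values.values())
        if hi - lo < 1e-12:
            return AAScale(self.accession, {aa: 0.5 for aa in self.values})
        return AAScale(
            self.accession, {aa: (v - lo) / (hi - lo) for aa, v in self.values.items()}
        )


def _scale(accession: str, ordered_values: list[float]) -> AAScale:
    """Build a scale from values in AAindex row order (A R N D C Q E G H I /
    L K M F P S T W Y V)."""
    return AAScale(accession, dict(zip(AAINDEX_ORDER, ordered_values)))


#: Residue order used by AAindex "I" blocks.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Normalized flexibility parameter (B-value), average. Vihinen et al. (1994).
VINM940101 = _scale(
    "VINM940101",
    [0.984, 1.008, 1.048, 1.068, 0.906, 1.037, 1.094, 1.031, 0.950, 0.927,
     0.935, 1.102, 0.952, 0.915, 1.049, 1.046, 0.997, 0.904, 0.929, 0.931],
)

# Polarity. Grantham (1974).
GRAR740102 = _scale(
    "GRAR740102",
    [8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2,
     4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9],
)

# Modified Kyte-Doolittle hydrophobicity scale. Juretic et al. (1998).
JURD980101 = _scale(
    "JURD980101",
    [1.10, -5.10, -3.50, -3.60, 2.50, -3.68, -3.20, -0.64, -3.20, 4.50,
     3.80, -4.11, 1.90, 2.80, -1.90, -0.50, -0.70, -0.46, -1.30, 4.20],
)

# Linker propensity index. Bae, Mallick & Elofsson (2005). Log-ratio
# convention as in derive_linker_index: negative = linker-preferring.
BAEK050101 = _scale(
    "BAEK050101",
    [0.0166, 0.0762, -0.0786, -0.1278, 0.5724, 0.1051, -0.1794, -0.0442,
     0.1643, 0.2758, 0.2523, -0.2134, 0.0197, 0.3561, -0.4188, -0.1629,
     -0.0701, 0.3836, 0.3836, 0.2500],
)

#: The default feature channels, in encoding order.
DEFAULT_SCALES: tuple[AAScale, ...] = (VINM940101, GRAR740102, JURD980101, BAEK050101)

_VENDORED = {s.accession: s for s in DEFAULT_SCALES}


def get_scale(accession: str) -> AAScale:
    """Return a vendored scale by accession."""
    try:
        return _VENDORED[accession]
    except KeyError:
        raise FormatError(f"no vendored scale with accession {accession!r}") from None


def read_aaindex(path: str | Path) -> dict[str, AAScale]:
    """Parse an AAindex flat file into scales keyed by accession.

    The format is line-oriented: ``H <accession>`` opens an entry, an ``I``
    line introduces two rows of ten values each (row order A R N D C Q E G H I
    then L K M F P S T W Y V), and ``//`` terminates the entry. Entries with
    ``NA`` values are skipped.
    """
    scales: dict[str, AAScale] = {}
    accession: str | None = None
    collecting = False
    numbers: list[float] = []
    skip = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                accession = line[2:].strip()
                numbers, collecting, skip = [], False, False
            elif line.startswith("I "):
                collecting = True
            elif line.startswith("//"):
                if accession and not skip:
                    if len(numbers) != 20:
                        raise FormatError(
                            f"AAindex entry {accession}: expected 20 values, "
                            f"got {len(numbers)}"
                        )
                    scales[accession] = _scale(accession, numbers)
                accession, collecting = None, False
            elif collecting and line[:1].isspace():
                for tok in line.split():
                    if tok == "NA":
                        skip = True
                    else:
                        try:
                            numbers.append(float(tok))
                        except ValueError as exc:
                            raise FormatError(
                                f"AAindex entry {accession}: bad value {tok!r}"
                            ) from exc
    if not scales:
        raise FormatError(f"no AAindex entries parsed from {path}")
    return scales
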