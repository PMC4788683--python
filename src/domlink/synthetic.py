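"""Synthetic proteins with planted domain/linker architecture.

The generator emulates the two statistical signals the feature set assumes:

1. *Composition bias* — linker regions prefer different residues than domain
   cores. Domain residues are drawn from a base composition; linker residues
   from the base composition tilted by ``exp(-beta * S0_i)`` (renormalized),
   where ``S0`` is a fixed reference linker-propensity vector (the vendored
   BAEK050101 scale, whose negative entries mark linker-preferring residues).
   ``beta = 0`` makes both compositions identical — no compositional signal.
2. *Disorder enrichment* — an external-disorder-predictor track is emulated
   by a per-residue Bernoulli draw whose success probability depends on the
   region (linkers are mostly disordered, domains mostly ordered).

Architectures are drawn independently per protein: 1–3 domains of 50–150
residues joined by 5–20 residue linkers, with terminal linkers appearing with
probability 0.8 on each end. Everything is driven by one seed, and file
output is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import (
    DisorderTrack,
    DomainDefinition,
    ProteinRecord,
    ResidueAnnotation,
    annotation_from_domains,
    write_annotations,
    write_disorder,
    write_fasta,
    write_segments,
)
from .errors import ConfigError
from .scales import BAEK050101

#: Residue order used for composition vectors.
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ArchitectureParams:
    """Generator settings; the defaults are the package's study conditions."""

    n_proteins: int = 150
    domains_per_protein: tuple[int, int] = (1, 3)
    domain_length: tuple[int, int] = (50, 150)
    linker_length: tuple[int, int] = (5, 20)
    terminal_linker_prob: float = 0.8
    beta: float = 3.0
    p_disorder_linker: float = 0.9
    p_disorder_domain: float = 0.1
    seed: int = 0
    base_composition: tuple[float, ...] | None = None  # order _AA; None = uniform

    def __post_init__(self) -> None:
        for name in ("domains_per_protein", "domain_length", "linker_length"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"invalid range {name}=({lo}, {hi})")
        for name in ("terminal_linker_prob", "p_disorder_linker", "p_disorder_domain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.base_composition is not None:
            comp = np.asarray(self.base_composition, dtype=float)
            if comp.shape != (20,) or (comp <= 0).any():
                raise ConfigError("base_composition must be 20 positive weights")
            object.__setattr__(
                self, "base_composition", tuple(comp / comp.sum())
            )

    def compositions(self) -> tuple[np.ndarray, np.ndarray]:
        """(domain, linker) residue distributions in `_AA` order."""
        if self.base_composition is None:
            base = np.full(20, 1 / 20)
        else:
            base = np.asarray(self.base_composition)
        s0 = np.array([BAEK050101.values[aa] for aa in _AA])
        tilt = base * np.exp(-self.beta * s0)
        return base, tilt / tilt.sum()


#: Reference propensity vector used for the composition tilt.
def reference_propensity() -> dict[str, float]:
    return dict(BAEK050101.values)


def sample_protein(
    params: ArchitectureParams, rng: np.random.Generator, protein_id: str
) -> tuple[ProteinRecord, ResidueAnnotation, DomainDefinition, DisorderTrack]:
    """Draw one protein: architecture, sequence, annotation, disorder track."""
    n_domains = int(rng.integers(params.domains_per_protein[0],
                                 params.domains_per_protein[1] + 1))
    dom_lens = rng.integers(params.domain_length[0], params.domain_length[1] + 1,
                            size=n_domains)
    # linkers: one between consecutive domains, optional at each terminus
    inner = rng.integers(params.linker_length[0], params.linker_length[1] + 1,
                         size=max(0, n_domains - 1))
    lead = (int(rng.integers(params.linker_length[0], params.linker_length[1] + 1))
            if rng.random() < params.terminal_linker_prob else 0)
    tail = (int(rng.integers(params.linker_length[0], params.linker_length[1] + 1))
            if rng.random() < params.terminal_linker_prob else 0)

    segments = []
    pos = 1 + lead
    for i, dlen in enumerate(dom_lens):
        segments.append((pos, pos + int(dlen) - 1))
        pos += int(dlen)
        if i < n_domains - 1:
            pos += int(inner[i])
    length = pos - 1 + tail
    domains = DomainDefinition(tuple(segments))
    annotation = annotation_from_domains(domains, length)

    is_domain = annotation.positive_mask()
    base, linker_comp = params.compositions()
    letters = np.frombuffer(_AA.encode(), dtype="S1")
    seq = np.empty(length, dtype="S1")
    n_dom = int(is_domain.sum())
    seq[is_domain] = rng.choice(letters, size=n_dom, p=base)
    seq[~is_domain] = rng.choice(letters, size=length - n_dom, p=linker_comp)
    sequence = seq.tobytes().decode()

    p_dis = np.where(is_domain, params.p_disorder_domain, params.p_disorder_linker)
    disorder = (rng.random(length) < p_dis).astype(float)

    return (
        ProteinRecord(id=protein_id, sequence=sequence),
        annotation,
        domains,
        DisorderTrack(tuple(disorder)),
    )


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    annotations: dict[str, ResidueAnnotation]
    domains: dict[str, DomainDefinition]
    disorder: dict[str, DisorderTrack]
    params: ArchitectureParams

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write FASTA + annotation/segment/disorder TSVs; byte-deterministic."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": directory / "proteins.fasta",
            "annotations": directory / "annotations.tsv",
            "segments": directory / "segments.tsv",
            "disorder": directory / "disorder.tsv",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_annotations(self.annotations, paths["annotations"])
        write_segments(self.domains, paths["segments"])
        write_disorder(self.disorder, paths["disorder"])
        return paths


def sample_dataset(params: ArchitectureParams) -> SyntheticDataset:
    """Generate a full dataset, deterministic in ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    proteins, annotations, domains, disorder = [], {}, {}, {}
    width = max(4, len(str(params.n_proteins)))
    for i in range(params.n_proteins):
        pid = f"syn{i:0{width}d}"
        rec, ann, doms, track = sample_protein(params, rng, pid)
        proteins.append(rec)
        annotations[pid] = ann
        domains[pid] = doms
        disorder[pid] = track
    return SyntheticDataset(proteins, annotations, domains, disorder, params)
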