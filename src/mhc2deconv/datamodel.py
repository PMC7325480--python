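"""Core domain types shared across the package.

Conventions used throughout:

* Amino-acid alphabet is the 20 canonical residues plus the wildcard ``X``,
  which encodes as a zero vector everywhere.
* Protein coordinates are 1-based and inclusive; a peptide of length L
  starting at position ``start`` occupies ``[start, start + L - 1]``.
* Peptide context ("PCI") is a 12-character string: 3 source residues
  upstream of the peptide, the first 3 peptide residues, the last 3 peptide
  residues, and 3 source residues downstream.  Peptides without a known
  source protein (e.g. binding-affinity assay peptides) carry no context,
  which is treated as 12 ``X`` wildcards by the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "X"
VALID_CHARS = frozenset(ALPHABET + WILDCARD)

CONTEXT_LEN = 12
PSEUDO_LEN = 34
CORE_LEN = 9

SOURCE_KINDS = ("BA", "EL_positive", "EL_negative")


def validate_sequence(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - VALID_CHARS
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)}: {seq!r}")


@dataclass
class PeptideRecord:
    """A peptide with its measurement label and optional source-protein context.

    ``source_kind`` distinguishes binding-affinity measurements (``BA``, with a
    log-transformed affinity target in [0, 1]) from eluted-ligand mass-spec
    observations (``EL_positive`` target 1, ``EL_negative`` target 0).
    """

    sequence: str
    source_kind: str
    target: float
    context: str | None = None
    source_protein_id: str | None = None
    start: int | None = None  # 1-based, inclusive
    allele: str | None = None  # restriction, when known (SA data)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_sequence(self.sequence, what="peptide")
        if len(self.sequence) < CORE_LEN:
            raise ValueError(
                f"peptide shorter than the {CORE_LEN}-residue binding core: {self.sequence!r}"
            )
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target {self.target} outside [0, 1]")
        if self.context is not None:
            self.context = self.context.upper()
            validate_sequence(self.context, what="context")
            if len(self.context) != CONTEXT_LEN:
                raise ValueError(
                    f"context must be {CONTEXT_LEN} characters, got {len(self.context)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlleleSpec:
    """An MHC-II allele and its fixed-length pseudo-sequence.

    The pseudo-sequence is the string of MHC residues lining the peptide
    binding groove; it is the allele's input representation in pan-specific
    models and is taken as input data, never recomputed here.
    """

    name: str
    pseudo_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pseudo_sequence", self.pseudo_sequence.upper())
        validate_sequence(self.pseudo_sequence, what="pseudo_sequence")


@dataclass
class DonorDataset:
    """Multi-allele eluted-ligand data from one donor.

    Positives are MS-observed ligands whose restricting allele among the
    donor's genotype is unknown; deconvolution fills ``annotations_pos`` /
    ``annotations_neg`` with one allele name per peptide.
    """

    donor_id: str
    alleles: list[AlleleSpec]
    positives: list[PeptideRecord]
    negatives: list[PeptideRecord] = field(default_factory=list)
    annotations_pos: list[str] | None = None
    annotations_neg: list[str] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 12:
            raise ValueError(f"donor must carry 1-12 alleles, got {len(self.alleles)}")
        lens = {len(a.pseudo_sequence) for a in self.alleles}
        if len(lens) > 1:
            raise ValueError(f"pseudo-sequence lengths differ within donor: {lens}")
        self.validate_annotations()

    @property
    def allele_names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def validate_annotations(self) -> None:
        names = set(self.allele_names)
        for ann, recs, label in (
            (self.annotations_pos, self.positives, "positive"),
            (self.annotations_neg, self.negatives, "negative"),
        ):
            if ann is None:
                continue
            if len(ann) != len(recs):
                raise ValueError(f"{label} annotation length mismatch")
            bad = set(ann) - names
            if bad:
                raise ValueError(f"{label} annotations outside donor genotype: {sorted(bad)}")


@dataclass
class ProteinRecord:
    """A protein sequence with a stable identifier (1-based positions)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has empty sequence")
        validate_sequence(self.sequence, what=f"protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PositionProfile:
    """A per-residue track over a protein, max-normalized to 1.

    ``kind`` is ``"mapps"`` for experimental ligand-coverage profiles and
    ``"promiscuity"`` for predicted allele-promiscuity profiles.
    """

    protein_id: str
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("mapps", "promiscuity"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("profile values must lie in [0, 1]")
        vmax = self.values.max() if self.values.size else 0.0
        if self.values.size and vmax not in (0.0,) and abs(vmax - 1.0) > 1e-9:
            raise ValueError("profile must be max-normalized to 1 (or all-zero)")

    def __len__(self) -> int:
        return len(self.values)


def max_normalize(values: np.ndarray) -> np.ndarray:
    """Divide by the maximum; an all-zero track is returned unchanged."""
    values = np.asarray(values, dtype=float)
    vmax = values.max() if values.size else 0.0
    return values / vmax if vmax > 0 else values.copy()
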