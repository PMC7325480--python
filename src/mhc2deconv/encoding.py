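"""Feature encoding for the core-alignment network.

Every (peptide, allele, core offset) triple maps to a fixed-length vector:

========================  =====  ==========================================
block                     dims   content
========================  =====  ==========================================
binding core              9x20   BLOSUM62 row of each core residue, / 5
flank lengths             2      min(left, 3)/3 and min(right, 3)/3
peptide length            9      one-hot over lengths 13-21 (clamped)
context (PCI)             12x20  BLOSUM62 rows of the 12 context residues
MHC pseudo-sequence       34x20  BLOSUM62 rows of the 34 groove residues
========================  =====  ==========================================

Total dimension 1111.  The wildcard ``X`` (and absent context) encodes as
zeros, contributing no signal.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from .datamodel import (
    ALPHABET,
    CONTEXT_LEN,
    CORE_LEN,
    AlleleSpec,
    PeptideRecord,
)

N_AA = 20
X_INDEX = N_AA  # wildcard row (all zeros) in the encoding table

LEN_MIN = 13
LEN_MAX = 21
N_LEN_BINS = LEN_MAX - LEN_MIN + 1

PSEUDO_LEN = 34

CORE_DIM = CORE_LEN * N_AA
FLANK_DIM = 2
CTX_DIM = CONTEXT_LEN * N_AA
PSEUDO_DIM = PSEUDO_LEN * N_AA
STATIC_DIM = N_LEN_BINS + CTX_DIM + PSEUDO_DIM
FEATURE_DIM = CORE_DIM + FLANK_DIM + STATIC_DIM  # 1111

_AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_AA_TO_INDEX["X"] = X_INDEX


def _build_blosum_table() -> np.ndarray:
    """(21, 20) table: scaled BLOSUM62 rows for the 20 residues, zeros for X."""
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((N_AA + 1, N_AA))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            table[i, j] = blosum[a, b] / 5.0
    return table


BLOSUM_TABLE = _build_blosum_table()


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to encoding-table row indices (X -> zero row)."""
    try:
        return np.array([_AA_TO_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"character {exc.args[0]!r} outside amino-acid alphabet") from exc


def encode_residues(seq: str) -> np.ndarray:
    """Flat BLOSUM encoding of a sequence, length len(seq)*20."""
    return BLOSUM_TABLE[seq_to_indices(seq)].ravel()


def length_onehot(length: int) -> np.ndarray:
    """One-hot over 13..21; lengths outside the range clamp to the nearest bin."""
    vec = np.zeros(N_LEN_BINS)
    vec[int(np.clip(length, LEN_MIN, LEN_MAX)) - LEN_MIN] = 1.0
    return vec


def flank_features(length: int, core_offset: int) -> np.ndarray:
    """Peptide-flanking-region lengths, each saturating at 3 and scaled to [0, 1]."""
    left = core_offset
    right = length - CORE_LEN - core_offset
    return np.array([min(left, 3) / 3.0, min(right, 3) / 3.0])


def encode(
    record: PeptideRecord, allele: AlleleSpec, core_offset: int
) -> np.ndarray:
    """Encode one peptide/allele pair at a given core offset.

    Raises ``ValueError`` when the offset does not fit the peptide or the
    pseudo-sequence length is not 34.
    """
    length = len(record.sequence)
    if not 0 <= core_offset <= length - CORE_LEN:
        raise ValueError(
            f"core offset {core_offset} invalid for peptide of length {length}"
        )
    if len(allele.pseudo_sequence) != PSEUDO_LEN:
        raise ValueError(
            f"pseudo-sequence must be {PSEUDO_LEN} residues, got "
            f"{len(allele.pseudo_sequence)} for {allele.name}"
        )
    core = record.sequence[core_offset : core_offset + CORE_LEN]
    context = record.context if record.context is not None else "X" * CONTEXT_LEN
    return np.concatenate(
        [
            encode_residues(core),
            flank_features(length, core_offset),
            length_onehot(length),
            encode_residues(context),
            encode_residues(allele.pseudo_sequence),
        ]
    )


def make_context(
    protein_seq: str, start0: int, length: int
) -> str:
    """Build the 12-char context for a peptide at 0-based ``start0`` in a protein.

    Positions beyond the protein termini are padded with ``X``.
    """
    end0 = start0 + length  # exclusive
    if start0 < 0 or end0 > len(protein_seq):
        raise ValueError("peptide window outside protein")
    up = protein_seq[max(start0 - 3, 0) : start0].rjust(3, "X")
    down = protein_seq[end0 : end0 + 3].ljust(3, "X")
    pep = protein_seq[start0:end0]
    return up + pep[:3] + pep[-3:] + down


class PackedPeptides:
    """Columnar container for batched network evaluation.

    Holds residue-index arrays padded to a common length plus precomputed
    context/length feature blocks; the allele (pseudo-sequence) block is
    supplied separately so the same peptides can be scored against many
    alleles without re-encoding.
    """

    def __init__(self, records: list[PeptideRecord]):
        if not records:
            raise ValueError("cannot pack an empty record list")
        self.records = records
        self.n = len(records)
        lengths = np.array([len(r.sequence) for r in records], dtype=np.int64)
        self.lengths = lengths
        self.max_len = int(lengths.max())
        self.n_offsets = lengths - CORE_LEN + 1
        self.max_offsets = int(self.n_offsets.max())

        # residue indices padded with the wildcard row
        idx = np.full((self.n, self.max_len), X_INDEX, dtype=np.int64)
        for i, r in enumerate(records):
            idx[i, : lengths[i]] = seq_to_indices(r.sequence)
        self.indices = idx

        # sliding windows of core indices, (n, max_offsets, 9); invalid offsets masked
        offs = np.arange(self.max_offsets)
        win = offs[None, :, None] + np.arange(CORE_LEN)[None, None, :]
        win = np.minimum(win, self.max_len - 1)
        self.core_windows = np.take_along_axis(
            idx[:, None, :].repeat(self.max_offsets, axis=1), win, axis=2
        )
        self.offset_mask = offs[None, :] < self.n_offsets[:, None]

        # flank features per (peptide, offset)
        left = np.minimum(offs[None, :], 3) / 3.0
        right = np.minimum(lengths[:, None] - CORE_LEN - offs[None, :], 3) / 3.0
        right = np.clip(right, 0.0, 1.0)
        self.flanks = np.stack(
            [np.broadcast_to(left, (self.n, self.max_offsets)), right], axis=2
        )

        self.targets = np.array([r.target for r in records])

        len_block = np.zeros((self.n, N_LEN_BINS))
        bins = np.clip(lengths, LEN_MIN, LEN_MAX) - LEN_MIN
        len_block[np.arange(self.n), bins] = 1.0
        ctx_block = np.zeros((self.n, CTX_DIM))
        for i, r in enumerate(records):
            if r.context is not None:
                ctx_block[i] = encode_residues(r.context)
        self.static = np.hstack([len_block, ctx_block])  # (n, 9 + 240)

    def core_features(self, rows: np.ndarray) -> np.ndarray:
        """(len(rows), max_offsets, 180) BLOSUM features of all candidate cores."""
        return BLOSUM_TABLE[self.core_windows[rows]].reshape(
            len(rows), self.max_offsets, CORE_DIM
        )


def encode_pseudo(allele: AlleleSpec) -> np.ndarray:
    if len(allele.pseudo_sequence) != PSEUDO_LEN:
        raise ValueError(
            f"pseudo-sequence must be {PSEUDO_LEN} residues for {allele.name}"
        )
    return encode_residues(allele.pseudo_sequence)
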