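"""Percentile-rank calibration, in-silico digestion and presentation
profiles.

Raw network outputs are not comparable across alleles, so each allele is
calibrated against a large sample of random background peptides (flat length
distribution 13-21): a query's %Rank is the percentage of background
peptides scoring at least as high, making 1%Rank mean "within the top 1% of
random peptides for this allele".

A protein-drug is profiled by digesting it into all overlapping 13-21mers,
keeping per allele the peptides below a %Rank threshold, marking covered
positions at most once per allele, and summing across alleles.  The
resulting "allele promiscuity" track (max-normalized) highlights hotspot
regions presented by many MHC-II molecules of the donor cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AlleleSpec,
    PeptideRecord,
    PositionProfile,
    ProteinRecord,
    max_normalize,
)
from .encoding import LEN_MAX, LEN_MIN, make_context
from .trainer import NetworkEnsemble, predict_batch

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 100_000
DEFAULT_RANK_THRESHOLD = 1.0  # percent


@dataclass
class RankTable:
    """Empirical score distribution of random background peptides for one
    allele; maps a score to its %Rank (percentage of background >= score)."""

    allele: str
    sorted_scores: np.ndarray  # ascending

    def __post_init__(self) -> None:
        self.sorted_scores = np.sort(np.asarray(self.sorted_scores, dtype=float))
        if len(self.sorted_scores) < 100:
            raise ValueError("rank calibration needs at least 100 background scores")

    @property
    def n(self) -> int:
        return len(self.sorted_scores)

    def rank(self, scores) -> np.ndarray:
        """%Rank in (0, 100]; ties count as beaten (conservative)."""
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        n_ge = self.n - np.searchsorted(self.sorted_scores, scores, side="left")
        return np.maximum(n_ge, 1) * 100.0 / self.n


def sample_background_peptides(
    background_proteome: list[ProteinRecord],
    n_random: int,
    seed: int,
    min_len: int = LEN_MIN,
    max_len: int = LEN_MAX,
) -> list[PeptideRecord]:
    """Draw peptides flat over lengths min_len..max_len from random proteome
    positions, with their true 12-char context."""
    eligible = [p for p in background_proteome if len(p) >= max_len]
    if not eligible:
        raise ValueError(f"no background protein of length >= {max_len}")
    rng = np.random.default_rng(seed)
    weights = np.array([len(p) for p in eligible], dtype=float)
    weights /= weights.sum()
    lengths = rng.integers(min_len, max_len + 1, size=n_random)
    prot_idx = rng.choice(len(eligible), size=n_random, p=weights)
    out = []
    for ell, pi in zip(lengths, prot_idx):
        prot = eligible[pi]
        start0 = int(rng.integers(0, len(prot) - ell + 1))
        out.append(
            PeptideRecord(
                sequence=prot.sequence[start0 : start0 + int(ell)],
                source_kind="EL_negative",
                target=0.0,
                context=make_context(prot.sequence, start0, int(ell)),
                source_protein_id=prot.id,
                start=start0 + 1,
            )
        )
    return out


def calibrate_rank(
    ensemble: NetworkEnsemble,
    allele: AlleleSpec,
    background_proteome: list[ProteinRecord],
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
) -> RankTable:
    """Score ``n_random`` random background peptides for one allele and store
    their empirical score distribution."""
    if n_random < 100:
        raise ValueError("n_random < 100 gives an unusable calibration")
    peptides = sample_background_peptides(background_proteome, n_random, seed)
    scores, _ = predict_batch(ensemble, peptides, allele)
    return RankTable(allele=allele.name, sorted_scores=scores)


def digest_protein(
    protein: ProteinRecord, min_len: int = LEN_MIN, max_len: int = LEN_MAX
) -> list[PeptideRecord]:
    """All overlapping windows of every length in [min_len, max_len], each
    with context (X-padded at the termini) and 1-based start position."""
    plen = len(protein)
    if plen < min_len:
        logger.warning(
            "protein %s shorter than %d residues; empty digest", protein.id, min_len
        )
        return []
    out = []
    for ell in range(min_len, min(max_len, plen) + 1):
        for start0 in range(plen - ell + 1):
            out.append(
                PeptideRecord(
                    sequence=protein.sequence[start0 : start0 + ell],
                    source_kind="EL_negative",
                    target=0.0,
                    context=make_context(protein.sequence, start0, ell),
                    source_protein_id=protein.id,
                    start=start0 + 1,
                )
            )
    return out


def _find_occurrences(peptide: str, protein_seq: str) -> list[int]:
    """0-based start positions of every exact occurrence."""
    hits, pos = [], protein_seq.find(peptide)
    while pos != -1:
        hits.append(pos)
        pos = protein_seq.find(peptide, pos + 1)
    return hits


def build_mapps_profile(
    peptides_by_donor: dict[str, list[str]],
    protein: ProteinRecord,
    min_len: int = 12,
) -> PositionProfile:
    """Coverage profile of experimentally eluted (MAPPs) peptides.

    Per donor, duplicate sequences are removed and peptides shorter than
    ``min_len`` (12, the shortest plausible MHC-II binder) are dropped; every
    exact occurrence of each remaining peptide increments the covered
    positions.  The track is max-normalized to 1.
    """
    counts = np.zeros(len(protein))
    n_unmapped = 0
    for donor, peptides in peptides_by_donor.items():
        unique = sorted(set(p.upper() for p in peptides))
        for pep in unique:
            if len(pep) < min_len:
                continue
            occ = _find_occurrences(pep, protein.sequence)
            if not occ:
                n_unmapped += 1
                logger.warning("peptide %s (donor %s) not found in %s", pep, donor, protein.id)
                continue
            for start0 in occ:
                counts[start0 : start0 + len(pep)] += 1
    if n_unmapped:
        logger.warning("%d peptide(s) could not be mapped to %s", n_unmapped, protein.id)
    return PositionProfile(
        protein_id=protein.id, values=max_normalize(counts), kind="mapps"
    )


def allele_promiscuity_counts(
    spans_by_allele: dict[str, list[tuple[int, int]]],
    protein_length: int,
) -> np.ndarray:
    """Pre-normalization promiscuity track from per-allele peptide spans.

    Spans are 1-based inclusive.  Within each allele a position counts at
    most once no matter how many peptides cover it; the per-allele binary
    maps are then summed, so a position covered by peptides from three
    alleles has promiscuity 3.
    """
    total = np.zeros(protein_length)
    for allele, spans in spans_by_allele.items():
        covered = np.zeros(protein_length, dtype=bool)
        for start, end in spans:
            if not 1 <= start <= end <= protein_length:
                raise ValueError(
                    f"span ({start}, {end}) outside protein of length {protein_length}"
                )
            covered[start - 1 : end] = True
        total += covered
    return total


def build_promiscuity_profile(
    ensemble: NetworkEnsemble,
    rank_tables: dict[str, RankTable],
    protein: ProteinRecord,
    alleles: list[AlleleSpec],
    rank_threshold: float = DEFAULT_RANK_THRESHOLD,
    min_len: int = LEN_MIN,
    max_len: int = LEN_MAX,
) -> PositionProfile:
    """Predicted allele-promiscuity profile of a protein.

    Digests the protein into overlapping 13-21mers, keeps per allele the
    peptides with %Rank <= ``rank_threshold``, caps coverage at one per
    allele per position, sums across alleles and max-normalizes.
    """
    for a in alleles:
        if a.name not in rank_tables and a.name.upper() not in rank_tables:
            raise ValueError(f"missing rank table for allele {a.name}")
    digest = digest_protein(protein, min_len, max_len)
    if not digest:
        return PositionProfile(
            protein_id=protein.id, values=np.zeros(len(protein)), kind="promiscuity"
        )
    spans_by_allele: dict[str, list[tuple[int, int]]] = {}
    for allele in alleles:
        table = rank_tables.get(allele.name, rank_tables.get(allele.name.upper()))
        scores, _ = predict_batch(ensemble, digest, allele)
        ranks = table.rank(scores)
        spans = [
            (rec.start, rec.start + len(rec.sequence) - 1)
            for rec, rank in zip(digest, ranks)
            if rank <= rank_threshold
        ]
        spans_by_allele[allele.name] = spans
    counts = allele_promiscuity_counts(spans_by_allele, len(protein))
    return PositionProfile(
        protein_id=protein.id, values=max_normalize(counts), kind="promiscuity"
    )
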