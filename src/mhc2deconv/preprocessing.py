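"""Dataset filters, negative augmentation and common-motif cross-validation
partitioning.

The eluted-ligand training data consist only of positives; negatives are
random peptides sampled from a background proteome with a flat length
distribution over 13-21, five times the count of the most abundant positive
length per length bin.  For a typically peaked ligand length distribution
(modal length around 22% of peptides) this yields the ~1:10
positive-to-negative ratio used throughout.

Cross-validation partitions are built with a Hobohm-style common-motif
clustering: any two peptides sharing an identical 9-mer belong to the same
cluster (transitive closure), and whole clusters are assigned to partitions,
so no 9-mer ever crosses a partition boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import PeptideRecord, ProteinRecord
from .encoding import LEN_MAX, LEN_MIN, make_context

logger = logging.getLogger(__name__)


def filter_by_length(
    records: list[PeptideRecord], min_len: int = 13, max_len: int = 21
) -> list[PeptideRecord]:
    """Keep only peptides with min_len <= L <= max_len (inclusive), in order."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r.sequence) <= max_len]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def exclude_drug_similar(
    records: list[PeptideRecord],
    drug_proteins: list[ProteinRecord],
    k: int = 9,
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Remove peptides sharing any identical k-mer with any drug protein.

    Used to strip training ligands that could bias evaluation on a protein
    drug: a peptide is removed iff one of its contiguous k-mers occurs
    verbatim in at least one drug chain.  Returns (kept, removed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not drug_proteins:
        raise ValueError("empty drug protein set; refusing to filter nothing")
    drug_kmers: set[str] = set()
    for prot in drug_proteins:
        drug_kmers |= _kmers(prot.sequence, k)
    kept, removed = [], []
    for rec in records:
        if any(
            rec.sequence[i : i + k] in drug_kmers
            for i in range(len(rec.sequence) - k + 1)
        ):
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def augment_negatives(
    positives: list[PeptideRecord],
    background_proteome: list[ProteinRecord],
    min_len: int = LEN_MIN,
    max_len: int = LEN_MAX,
    factor: int = 5,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Sample random-proteome negatives, flat over lengths min_len..max_len.

    Let m be the count of the most abundant positive length; each length bin
    receives factor*m negatives drawn (with replacement) from random
    positions of the background proteome, carrying their true 12-char
    context.  Total negatives = (max_len-min_len+1) * factor * m.
    """
    if not positives:
        raise ValueError("cannot augment an empty positive set")
    total_bg = sum(len(p) for p in background_proteome)
    if total_bg < max_len:
        raise ValueError("background proteome too short to sample from")
    lengths, counts = np.unique(
        [len(p.sequence) for p in positives], return_counts=True
    )
    m = int(counts.max())
    rng = np.random.default_rng(seed)
    eligible = [p for p in background_proteome if len(p) >= max_len]
    if not eligible:
        raise ValueError(f"no background protein of length >= {max_len}")
    weights = np.array([len(p) for p in eligible], dtype=float)
    weights /= weights.sum()
    negatives: list[PeptideRecord] = []
    for ell in range(min_len, max_len + 1):
        prot_idx = rng.choice(len(eligible), size=factor * m, p=weights)
        for pi in prot_idx:
            prot = eligible[pi]
            start0 = int(rng.integers(0, len(prot) - ell + 1))
            seq = prot.sequence[start0 : start0 + ell]
            negatives.append(
                PeptideRecord(
                    sequence=seq,
                    source_kind="EL_negative",
                    target=0.0,
                    context=make_context(prot.sequence, start0, ell),
                    source_protein_id=prot.id,
                    start=start0 + 1,
                )
            )
    return negatives


@dataclass
class PartitionAssignment:
    """Cluster and partition labels per peptide index."""

    partition: np.ndarray  # int, in {0..n_partitions-1}
    cluster: np.ndarray  # int cluster ids

    def __len__(self) -> int:
        return len(self.partition)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def hobohm_partition(
    records: list[PeptideRecord],
    k: int = 9,
    n_partitions: int = 5,
    seed: int = 0,
) -> PartitionAssignment:
    """Common-motif clustering into cross-validation partitions.

    Peptides sharing any identical k-mer are linked; clusters are the
    transitive closure of that relation.  Whole clusters are then assigned
    greedily -- largest first, ties by smallest cluster id -- to the
    currently smallest partition, keeping fold sizes near-equal while
    guaranteeing zero cross-partition k-mer sharing.  ``seed`` is accepted
    for interface symmetry; the assignment is fully deterministic.
    """
    if n_partitions < 2:
        raise ValueError("need at least 2 partitions")
    for r in records:
        if len(r.sequence) < k:
            raise ValueError(f"peptide shorter than the {k}-mer motif: {r.sequence!r}")
    n = len(records)
    uf = _UnionFind(n)
    seen: dict[str, int] = {}
    for i, rec in enumerate(records):
        for kmer in _kmers(rec.sequence, k):
            j = seen.setdefault(kmer, i)
            if j != i:
                uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(n)], dtype=np.int64)
    # renumber clusters by first appearance
    _, cluster = np.unique(roots, return_inverse=True)

    sizes = np.bincount(cluster)
    order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], c))
    part_of_cluster = np.empty(len(sizes), dtype=np.int64)
    loads = np.zeros(n_partitions, dtype=np.int64)
    for c in order:
        p = int(np.argmin(loads))
        part_of_cluster[c] = p
        loads[p] += sizes[c]
    return PartitionAssignment(partition=part_of_cluster[cluster], cluster=cluster)
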