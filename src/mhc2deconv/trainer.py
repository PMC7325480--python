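"""Training orchestration: single-allele pre-training, iterative multi-allele
annotation, and cross-validated ensemble training.

The procedure works in two steps.  Networks are first pre-trained on
single-allele (SA) data only, which -- thanks to the pan-specific
pseudo-sequence input -- gives every allele an initial binding motif.  The
multi-allele (MA) eluted ligands are then annotated: each positive is
assigned the donor allele with the highest raw prediction score, converting
it into pseudo-SA data, while each negative receives a random donor allele
so that negative signal is spread evenly rather than punishing the current
best motif.  One training epoch over SA plus annotated MA data follows, the
MA data are re-annotated, and the cycle repeats.  Every (initialization
seed, hidden-layer size, held-out partition) combination yields one network;
the default grid of 10 seeds x {20, 40, 60} hidden units x 5 partitions
gives an ensemble of 150 networks whose average is the final prediction.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datamodel import AlleleSpec, DonorDataset, PeptideRecord
from .encoding import PackedPeptides, encode_pseudo
from .network import Network, NetworkConfig
from .preprocessing import PartitionAssignment, hobohm_partition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    seeds: tuple[int, ...] = tuple(range(1, 11))
    hidden_grid: tuple[int, ...] = (20, 40, 60)
    n_partitions: int = 5

    @property
    def size(self) -> int:
        return len(self.seeds) * len(self.hidden_grid) * self.n_partitions

    def jobs(self):
        """(seed, hidden_units, held-out fold) triples, in deterministic order."""
        return itertools.product(self.seeds, self.hidden_grid, range(self.n_partitions))


@dataclass
class EnsembleMember:
    network: Network
    seed: int
    hidden: int
    fold: int


@dataclass
class NetworkEnsemble:
    """A trained grid of networks plus the bookkeeping needed for honest
    cross-validated evaluation (which partition each member never saw)."""

    members: list[EnsembleMember]
    alleles: dict[str, AlleleSpec]
    n_partitions: int
    sa_partition: np.ndarray | None = None
    ma_partition: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    rank_tables: dict = field(default_factory=dict)  # filled by rank calibration

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble has no members")

    def allele_spec(self, name: str) -> AlleleSpec:
        try:
            return self.alleles[name.upper()]
        except KeyError:
            raise KeyError(f"allele {name!r} unknown to this ensemble") from None


def _resolve_alleles(
    ma_donors: list[DonorDataset],
    sa_records: list[PeptideRecord],
    extra_alleles: dict[str, AlleleSpec] | None,
) -> dict[str, AlleleSpec]:
    table: dict[str, AlleleSpec] = {}
    for donor in ma_donors:
        for a in donor.alleles:
            table.setdefault(a.name.upper(), a)
    if extra_alleles:
        for k, v in extra_alleles.items():
            table.setdefault(k.upper(), v)
    missing = {
        r.allele for r in sa_records if r.allele and r.allele.upper() not in table
    }
    if missing:
        raise ValueError(f"no pseudo-sequence known for SA alleles: {sorted(missing)}")
    return table


class _TrainingData:
    """Packed view of SA + MA records with shared partition labels."""

    def __init__(
        self,
        sa_records: list[PeptideRecord],
        ma_donors: list[DonorDataset],
        alleles: dict[str, AlleleSpec],
        partition_seed: int,
    ):
        for r in sa_records:
            if r.allele is None:
                raise ValueError("every SA record must carry an allele")
        self.allele_names = sorted(alleles)
        self.allele_pos = {a: i for i, a in enumerate(self.allele_names)}
        self.pseudo_mat = np.stack(
            [encode_pseudo(alleles[a]) for a in self.allele_names]
        )

        records: list[PeptideRecord] = list(sa_records)
        self.sa_rows = np.arange(len(sa_records))
        self.donor_rows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.donor_allele_idx: dict[str, np.ndarray] = {}
        for donor in ma_donors:
            pos_lo = len(records)
            records.extend(donor.positives)
            neg_lo = len(records)
            records.extend(donor.negatives)
            self.donor_rows[donor.donor_id] = (
                np.arange(pos_lo, neg_lo),
                np.arange(neg_lo, len(records)),
            )
            self.donor_allele_idx[donor.donor_id] = np.array(
                [self.allele_pos[a.name.upper()] for a in donor.alleles]
            )
        self.records = records
        self.packed = PackedPeptides(records)
        assignment: PartitionAssignment = hobohm_partition(
            records, k=9, n_partitions=5, seed=partition_seed
        )
        self.partition = assignment.partition
        self.sa_allele_idx = np.array(
            [self.allele_pos[r.allele.upper()] for r in sa_records], dtype=np.int64
        )

    def initial_allele_idx(self) -> np.ndarray:
        idx = np.zeros(self.packed.n, dtype=np.int64)
        idx[self.sa_rows] = self.sa_allele_idx
        return idx


def _annotate_rows(
    net: Network,
    data: _TrainingData,
    rows: np.ndarray,
    candidate_alleles: np.ndarray,
    reference_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Best allele index (into data.allele_names) per row.

    With ``reference_rows`` the per-allele scores are percentile-normalized
    against that background sample before the argmax, levelling out
    between-allele differences in raw score scale; without it the raw scores
    compete directly.  Ties favour the donor's first-listed allele.
    """
    scores = np.empty((len(candidate_alleles), len(rows)))
    for j, a in enumerate(candidate_alleles):
        idx = np.full(data.packed.n, a, dtype=np.int64)
        s, _ = net.score_subset(data.packed, rows, data.pseudo_mat, idx)
        if reference_rows is not None:
            ref, _ = net.score_subset(data.packed, reference_rows, data.pseudo_mat, idx)
            s = np.searchsorted(np.sort(ref), s, side="left") / len(ref)
        scores[j] = s
    return candidate_alleles[np.argmax(scores, axis=0)]


def annotate_ma(
    networks_for_fold: list[Network],
    donor_dataset: DonorDataset,
    seed: int = 0,
    rank_reference: list[PeptideRecord] | None = None,
) -> tuple[list[str], list[str]]:
    """Annotate a donor's MA data with per-peptide allele assignments.

    Positives receive the donor allele with the highest prediction score
    (averaged over the supplied networks); with ``rank_reference`` (a sample
    of random background peptides) each allele's scores are first
    percentile-normalized against that background, which makes scores
    comparable across alleles.  Negatives receive a donor allele drawn
    uniformly at random (reproducible under ``seed``).  Returns
    (positive annotations, negative annotations) as allele-name lists.
    """
    if not donor_dataset.alleles:
        raise ValueError("donor has no alleles")
    if not networks_for_fold:
        raise ValueError("need at least one network")
    names = donor_dataset.allele_names
    pseudo_mat = np.stack([encode_pseudo(a) for a in donor_dataset.alleles])
    pos_ann: list[str] = []
    if donor_dataset.positives:
        packed = PackedPeptides(donor_dataset.positives)
        rows = np.arange(packed.n)
        ref_packed = PackedPeptides(rank_reference) if rank_reference else None
        mean_scores = np.zeros((len(names), packed.n))
        for net in networks_for_fold:
            for j in range(len(names)):
                idx = np.full(packed.n, j, dtype=np.int64)
                s, _ = net.score_subset(packed, rows, pseudo_mat, idx)
                if ref_packed is not None:
                    ridx = np.full(ref_packed.n, j, dtype=np.int64)
                    ref, _ = net.score_subset(
                        ref_packed, np.arange(ref_packed.n), pseudo_mat, ridx
                    )
                    s = np.searchsorted(np.sort(ref), s, side="left") / len(ref)
                mean_scores[j] += s
        pos_ann = [names[j] for j in np.argmax(mean_scores, axis=0)]
    rng = np.random.default_rng(seed)
    neg_ann = [names[j] for j in rng.integers(0, len(names), len(donor_dataset.negatives))]
    return pos_ann, neg_ann


def train_nnalign_mac(
    sa_records: list[PeptideRecord],
    ma_donors: list[DonorDataset],
    ensemble_config: EnsembleConfig,
    run_config: NetworkConfig,
    extra_alleles: dict[str, AlleleSpec] | None = None,
) -> NetworkEnsemble:
    """Train the full cross-validated ensemble.

    For each (seed, hidden-units, held-out fold) job: pre-train
    ``epochs_pretrain`` epochs on SA data outside the fold, then alternate MA
    annotation and one epoch of training on SA plus annotated MA data
    (outside the fold) until ``epochs_total`` epochs have run.
    """
    if not sa_records:
        raise ValueError("pre-training requires at least one SA record")
    alleles = _resolve_alleles(ma_donors, sa_records, extra_alleles)
    data = _TrainingData(sa_records, ma_donors, alleles, run_config.seed)

    ma_pos_rows = (
        np.concatenate([data.donor_rows[d.donor_id][0] for d in ma_donors])
        if ma_donors
        else np.empty(0, dtype=np.int64)
    )
    ma_neg_rows = (
        np.concatenate([data.donor_rows[d.donor_id][1] for d in ma_donors])
        if ma_donors
        else np.empty(0, dtype=np.int64)
    )

    members: list[EnsembleMember] = []
    for seed, hidden, fold in ensemble_config.jobs():
        ss = np.random.SeedSequence([run_config.seed, seed, hidden, fold])
        net_seed = int(ss.generate_state(1)[0] % (2**31))
        cfg = replace(run_config, seed=net_seed, hidden_units=hidden)
        net = Network(cfg)
        rng = np.random.default_rng(ss.spawn(1)[0])

        sa_train = data.sa_rows[data.partition[data.sa_rows] != fold]
        if len(sa_train) == 0:
            raise ValueError(f"fold {fold} leaves no SA training examples")
        sa_idx_full = _full_sa_idx(data)
        for epoch in range(cfg.epochs_pretrain):
            net.train_epoch(
                data.packed, data.pseudo_mat, sa_idx_full, rng,
                rows=sa_train, center_core=epoch < cfg.burnin_epochs,
            )

        allele_idx = data.initial_allele_idx()
        ma_train_rows = np.concatenate([sa_train,
                                        ma_pos_rows[data.partition[ma_pos_rows] != fold] if len(ma_pos_rows) else np.empty(0, dtype=np.int64),
                                        ma_neg_rows[data.partition[ma_neg_rows] != fold] if len(ma_neg_rows) else np.empty(0, dtype=np.int64)])
        # MA negatives are flat-length random proteome peptides: a fixed
        # subsample serves as the per-allele rank-normalization background
        # during annotation, preventing one allele from absorbing all ligands
        ref_rows = None
        if len(ma_neg_rows):
            n_ref = min(2000, len(ma_neg_rows))
            ref_rows = rng.choice(ma_neg_rows, size=n_ref, replace=False)
        n_prev = None
        for cycle in range(cfg.epochs_pretrain, cfg.epochs_total):
            changed = 0
            for donor in ma_donors:
                pos_rows, neg_rows = data.donor_rows[donor.donor_id]
                cand = data.donor_allele_idx[donor.donor_id]
                if len(pos_rows):
                    new = _annotate_rows(net, data, pos_rows, cand, reference_rows=ref_rows)
                    changed += int(np.sum(new != allele_idx[pos_rows]))
                    allele_idx[pos_rows] = new
                if len(neg_rows):
                    allele_idx[neg_rows] = cand[rng.integers(0, len(cand), len(neg_rows))]
            if n_prev is not None and changed == 0:
                logger.debug("cycle %d: annotation converged", cycle)
            n_prev = changed
            logger.debug("cycle %d: %d annotation changes", cycle, changed)
            net.train_epoch(
                data.packed, data.pseudo_mat, allele_idx, rng,
                rows=ma_train_rows, center_core=cycle < cfg.burnin_epochs,
            )
        members.append(EnsembleMember(network=net, seed=seed, hidden=hidden, fold=fold))
        logger.info("trained network seed=%d hidden=%d fold=%d", seed, hidden, fold)

    ensemble = NetworkEnsemble(
        members=members,
        alleles=alleles,
        n_partitions=ensemble_config.n_partitions,
        sa_partition=data.partition[data.sa_rows],
        ma_partition={
            d.donor_id: (
                data.partition[data.donor_rows[d.donor_id][0]],
                data.partition[data.donor_rows[d.donor_id][1]],
            )
            for d in ma_donors
        },
    )
    return ensemble


def _full_sa_idx(data: _TrainingData) -> np.ndarray:
    idx = np.zeros(data.packed.n, dtype=np.int64)
    idx[data.sa_rows] = data.sa_allele_idx
    return idx


def predict_batch(
    ensemble: NetworkEnsemble,
    records: list[PeptideRecord],
    allele: AlleleSpec,
    members: list[EnsembleMember] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble scores for many peptides against one allele.

    The peptide score is the arithmetic mean over member scores (each
    member's best-core output).  The reported core offset is the offset
    preferred by the average of per-offset member outputs.  Returns
    (scores, offsets).
    """
    if members is None:
        members = ensemble.members
    if not members:
        raise ValueError("no ensemble members to average")
    packed = PackedPeptides(records)
    pseudo = encode_pseudo(allele)[None, :]
    zeros = np.zeros(packed.n, dtype=np.int64)
    rows = np.arange(packed.n)
    mean_best = np.zeros(packed.n)
    mean_per_offset = np.zeros((packed.n, packed.max_offsets))
    for m in members:
        for lo in range(0, packed.n, 2048):
            chunk = rows[lo : lo + 2048]
            out = m.network.score_all_offsets(packed, chunk, pseudo, zeros)
            mean_best[chunk] += np.max(out, axis=1)
            mean_per_offset[chunk] += np.where(np.isfinite(out), out, 0.0)
    mean_best /= len(members)
    offsets = np.argmax(
        np.where(packed.offset_mask, mean_per_offset, -np.inf), axis=1
    )
    return mean_best, offsets


def predict(
    ensemble: NetworkEnsemble,
    record: PeptideRecord,
    allele: AlleleSpec,
    members: list[EnsembleMember] | None = None,
) -> float:
    """Mean over member scores for one peptide/allele pair."""
    scores, _ = predict_batch(ensemble, [record], allele, members)
    return float(scores[0])


def cross_validate(
    ensemble: NetworkEnsemble, ma_donors: list[DonorDataset]
) -> dict[str, float]:
    """Held-out AUC0.1 per donor.

    Each peptide is scored only by ensemble members whose held-out partition
    contains it, taking the maximum over the donor's alleles of the
    member-averaged score; positives and negatives are then ranked together.
    """
    from .evaluation import auc01

    results: dict[str, float] = {}
    for donor in ma_donors:
        if donor.donor_id not in ensemble.ma_partition:
            raise ValueError(f"donor {donor.donor_id!r} was not part of training")
        pos_part, neg_part = ensemble.ma_partition[donor.donor_id]
        records = donor.positives + donor.negatives
        parts = np.concatenate([pos_part, neg_part])
        labels = np.concatenate(
            [np.ones(len(donor.positives)), np.zeros(len(donor.negatives))]
        )
        best = np.full(len(records), -np.inf)
        for allele in donor.alleles:
            scores = np.zeros(len(records))
            for fold in range(ensemble.n_partitions):
                fold_members = [m for m in ensemble.members if m.fold == fold]
                mask = parts == fold
                if not mask.any() or not fold_members:
                    continue
                sub = [records[i] for i in np.flatnonzero(mask)]
                s, _ = predict_batch(ensemble, sub, allele, members=fold_members)
                scores[mask] = s
            best = np.maximum(best, scores)
        results[donor.donor_id] = auc01(labels, best)
    return results


def save_ensemble(ensemble: NetworkEnsemble, directory) -> None:
    """Write an ensemble as a directory: a JSON manifest plus one versioned
    .npz weight archive per member."""
    from .network import save_network

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "n_partitions": ensemble.n_partitions,
        "alleles": {
            k: v.pseudo_sequence for k, v in sorted(ensemble.alleles.items())
        },
        "members": [
            {"file": f"member_{i:03d}.npz", "seed": m.seed, "hidden": m.hidden, "fold": m.fold}
            for i, m in enumerate(ensemble.members)
        ],
        "sa_partition": (
            ensemble.sa_partition.tolist() if ensemble.sa_partition is not None else None
        ),
        "ma_partition": {
            d: [p.tolist(), n.tolist()] for d, (p, n) in ensemble.ma_partition.items()
        },
        "rank_tables": {
            name: table.sorted_scores.tolist()
            for name, table in ensemble.rank_tables.items()
        },
    }
    with open(directory / "ensemble.json", "w") as fh:
        json.dump(manifest, fh)
    for i, m in enumerate(ensemble.members):
        save_network(m.network, directory / f"member_{i:03d}.npz")


def load_ensemble(directory) -> NetworkEnsemble:
    from .profiles import RankTable
    from .network import load_network

    directory = Path(directory)
    with open(directory / "ensemble.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != 1:
        raise ValueError("unsupported ensemble format version")
    members = [
        EnsembleMember(
            network=load_network(directory / meta["file"]),
            seed=meta["seed"],
            hidden=meta["hidden"],
            fold=meta["fold"],
        )
        for meta in manifest["members"]
    ]
    ensemble = NetworkEnsemble(
        members=members,
        alleles={
            k: AlleleSpec(name=k, pseudo_sequence=ps)
            for k, ps in manifest["alleles"].items()
        },
        n_partitions=manifest["n_partitions"],
        sa_partition=(
            np.array(manifest["sa_partition"])
            if manifest["sa_partition"] is not None
            else None
        ),
        ma_partition={
            d: (np.array(p), np.array(n))
            for d, (p, n) in manifest["ma_partition"].items()
        },
    )
    ensemble.rank_tables = {
        name: RankTable(allele=name, sorted_scores=np.array(scores))
        for name, scores in manifest.get("rank_tables", {}).items()
    }
    return ensemble
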