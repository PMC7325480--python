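"""A single shallow core-alignment network trained on mixed BA/EL targets.

The network scores a (peptide, allele) pair by evaluating every possible
placement of the 9-residue binding core along the peptide and taking the
best-scoring placement (hard max alignment).  Training is plain stochastic
gradient descent on squared error between the sigmoid output and the target;
the gradient flows only through the max-scoring core, which is recomputed at
every presentation so the alignment co-evolves with the weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import CORE_LEN, AlleleSpec, PeptideRecord
from .encoding import (
    CORE_DIM,
    FEATURE_DIM,
    FLANK_DIM,
    PSEUDO_DIM,
    PackedPeptides,
    encode_pseudo,
)

BA_TRANSFORM_BASE = 50000.0  # IC50 (nM) mapping to target 0

# layout of the flattened feature vector
_CORE = slice(0, CORE_DIM)
_FLANK = slice(CORE_DIM, CORE_DIM + FLANK_DIM)
_STATIC = slice(CORE_DIM + FLANK_DIM, FEATURE_DIM - PSEUDO_DIM)
_PSEUDO = slice(FEATURE_DIM - PSEUDO_DIM, FEATURE_DIM)


def transform_ba_target(ic50_nm: float) -> float:
    """Map an IC50 in nM to a [0, 1] training target.

    Uses the standard log transform 1 - log(IC50)/log(50000), clipped to
    [0, 1]: 50000 nM (non-binder) maps to 0 and 1 nM to 1.
    """
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return float(np.clip(1.0 - math.log(ic50_nm) / math.log(BA_TRANSFORM_BASE), 0.0, 1.0))


@dataclass
class NetworkConfig:
    hidden_units: int = 40
    seed: int = 1
    learning_rate: float = 0.05
    epochs_pretrain: int = 20
    epochs_total: int = 50
    burnin_epochs: int = 25  # global epoch count with centre-pinned cores
    core_length: int = CORE_LEN
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs_pretrain > self.epochs_total:
            raise ValueError("epochs_pretrain cannot exceed epochs_total")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.core_length != CORE_LEN:
            raise ValueError("only 9-residue binding cores are supported")


@dataclass
class CoreAlignment:
    """Best core placement for one peptide/allele pair."""

    offset: int  # 0-based within the peptide
    core: str
    score: float


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Network:
    """Shallow feed-forward network: 1111 inputs, one sigmoid hidden layer,
    one sigmoid output."""

    config: NetworkConfig
    w1: np.ndarray = field(repr=False, default=None)  # (H, 1111)
    b1: np.ndarray = field(repr=False, default=None)  # (H,)
    w2: np.ndarray = field(repr=False, default=None)  # (H,)
    b2: float = 0.0

    def __post_init__(self) -> None:
        if self.w1 is None:
            rng = np.random.default_rng(self.config.seed)
            h = self.config.hidden_units
            self.w1 = rng.uniform(-0.05, 0.05, size=(h, FEATURE_DIM))
            self.b1 = rng.uniform(-0.05, 0.05, size=h)
            self.w2 = rng.uniform(-0.05, 0.05, size=h)
            self.b2 = float(rng.uniform(-0.05, 0.05))

    # ------------------------------------------------------------------ scoring

    def _hidden_pre_all_offsets(
        self,
        packed: PackedPeptides,
        rows: np.ndarray,
        pseudo_mat: np.ndarray,
        allele_idx: np.ndarray,
    ) -> np.ndarray:
        """(B, O, H) hidden pre-activations for every candidate core offset."""
        core = packed.core_features(rows)  # (B, O, 180)
        flank = packed.flanks[rows]  # (B, O, 2)
        static_h = packed.static[rows] @ self.w1[:, _STATIC].T  # (B, H)
        pseudo_h = pseudo_mat @ self.w1[:, _PSEUDO].T  # (A, H)
        pre = np.einsum("bof,hf->boh", core, self.w1[:, _CORE], optimize=True)
        pre += np.einsum("bof,hf->boh", flank, self.w1[:, _FLANK])
        pre += (static_h + pseudo_h[allele_idx[rows]])[:, None, :]
        pre += self.b1
        return pre

    def score_all_offsets(
        self,
        packed: PackedPeptides,
        rows: np.ndarray,
        pseudo_mat: np.ndarray,
        allele_idx: np.ndarray,
    ) -> np.ndarray:
        """(B, O) network outputs; invalid offsets are -inf."""
        h = _sigmoid(self._hidden_pre_all_offsets(packed, rows, pseudo_mat, allele_idx))
        out = _sigmoid(h @ self.w2 + self.b2)
        return np.where(packed.offset_mask[rows], out, -np.inf)

    def score_subset(
        self,
        packed: PackedPeptides,
        rows: np.ndarray,
        pseudo_mat: np.ndarray,
        allele_idx: np.ndarray,
        batch_size: int = 1024,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Score the given packed rows; returns (scores, best_offsets).

        Ties between offsets resolve to the smallest offset.
        """
        rows = np.asarray(rows, dtype=np.int64)
        scores = np.empty(len(rows))
        offsets = np.empty(len(rows), dtype=np.int64)
        for lo in range(0, len(rows), batch_size):
            chunk = rows[lo : lo + batch_size]
            out = self.score_all_offsets(packed, chunk, pseudo_mat, allele_idx)
            best = np.argmax(out, axis=1)
            offsets[lo : lo + batch_size] = best
            scores[lo : lo + batch_size] = out[np.arange(len(chunk)), best]
        return scores, offsets

    def score_packed(
        self,
        packed: PackedPeptides,
        pseudo_mat: np.ndarray,
        allele_idx: np.ndarray,
        batch_size: int = 1024,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Score every packed peptide; returns (scores, best_offsets)."""
        return self.score_subset(
            packed, np.arange(packed.n), pseudo_mat, allele_idx, batch_size
        )

    def score_peptide(
        self, record: PeptideRecord, allele: AlleleSpec
    ) -> CoreAlignment:
        """Evaluate all L-8 core placements and return the best one."""
        packed = PackedPeptides([record])
        pseudo = encode_pseudo(allele)[None, :]
        scores, offsets = self.score_packed(packed, pseudo, np.zeros(1, dtype=np.int64))
        off = int(offsets[0])
        return CoreAlignment(
            offset=off,
            core=record.sequence[off : off + CORE_LEN],
            score=float(scores[0]),
        )

    # ----------------------------------------------------------------- training

    def train_epoch(
        self,
        packed: PackedPeptides,
        pseudo_mat: np.ndarray,
        allele_idx: np.ndarray,
        rng: np.random.Generator,
        rows: np.ndarray | None = None,
        center_core: bool = False,
    ) -> float:
        """One shuffled SGD pass over ``rows`` (default: all examples);
        returns the mean squared error observed (computed on each mini-batch
        before its update).

        With ``center_core`` the binding core is pinned to the central
        window instead of the max-scoring one -- the alignment burn-in that
        prevents the register from committing to an arbitrary shift before
        the motif has formed."""
        rows_all = np.arange(packed.n) if rows is None else np.asarray(rows, dtype=np.int64)
        if len(rows_all) == 0:
            raise ValueError("cannot train on an empty example set")
        order = rows_all[rng.permutation(len(rows_all))]
        lr = self.config.learning_rate
        bs = self.config.batch_size
        sse = 0.0
        for lo in range(0, len(order), bs):
            rows = order[lo : lo + bs]
            nb = len(rows)
            pre = self._hidden_pre_all_offsets(packed, rows, pseudo_mat, allele_idx)
            h_all = _sigmoid(pre)
            out_all = _sigmoid(h_all @ self.w2 + self.b2)
            out_all = np.where(packed.offset_mask[rows], out_all, -np.inf)
            if center_core:
                best = (packed.n_offsets[rows] - 1) // 2
            else:
                best = np.argmax(out_all, axis=1)  # smallest offset on ties

            ar = np.arange(nb)
            h = h_all[ar, best]  # (B, H)
            y = out_all[ar, best]
            t = packed.targets[rows]
            err = y - t
            sse += float(np.sum(err**2))

            x = np.empty((nb, FEATURE_DIM))
            x[:, _CORE] = packed.core_features(rows)[ar, best]
            x[:, _FLANK] = packed.flanks[rows][ar, best]
            x[:, _STATIC] = packed.static[rows]
            x[:, _PSEUDO] = pseudo_mat[allele_idx[rows]]

            delta2 = err * y * (1.0 - y)  # (B,)
            delta1 = (delta2[:, None] * self.w2[None, :]) * h * (1.0 - h)
            if not (np.all(np.isfinite(delta1)) and np.all(np.isfinite(delta2))):
                raise FloatingPointError("non-finite gradient encountered")

            # summed (not averaged) batch gradient: with small batches this
            # approximates per-example online SGD at the same learning rate
            self.w2 -= lr * (h.T @ delta2)
            self.b2 -= lr * float(delta2.sum())
            self.w1 -= lr * (delta1.T @ x)
            self.b1 -= lr * delta1.sum(axis=0)
        return sse / len(order)


def save_network(net: Network, path) -> None:
    """Serialize weights and config to a versioned .npz archive."""
    np.savez(
        path,
        version=np.array([1]),
        w1=net.w1,
        b1=net.b1,
        w2=net.w2,
        b2=np.array([net.b2]),
        config=np.array(
            [
                net.config.hidden_units,
                net.config.seed,
                net.config.epochs_pretrain,
                net.config.epochs_total,
                net.config.batch_size,
            ],
            dtype=np.int64,
        ),
        learning_rate=np.array([net.config.learning_rate]),
    )


def load_network(path) -> Network:
    data = np.load(path)
    if int(data["version"][0]) != 1:
        raise ValueError("unsupported network file version")
    hu, seed, ep, et, bs = (int(v) for v in data["config"])
    cfg = NetworkConfig(
        hidden_units=hu,
        seed=seed,
        learning_rate=float(data["learning_rate"][0]),
        epochs_pretrain=ep,
        epochs_total=et,
        batch_size=bs,
    )
    return Network(
        config=cfg,
        w1=data["w1"],
        b1=data["b1"],
        w2=data["w2"],
        b2=float(data["b2"][0]),
    )
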