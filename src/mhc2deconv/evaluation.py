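"""Evaluation statistics: profile correlations, early-ROC AUC, expanded-core
labelling, PPV, precision-recall scans, bootstrap profile comparison,
Kullback-Leibler sequence logos, amino-acid frequency comparison and the
ELISpot positivity rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import CORE_LEN

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- correlations


def profile_scc(profile_a, profile_b) -> float:
    """Spearman rank correlation between two per-position tracks.

    Ties get average ranks.  A constant track has no rank ordering; NaN is
    returned with a warning.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("constant profile; Spearman correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(a, b)
    return float(rho)


def auc01(labels, scores, normalized: bool = True) -> float:
    """ROC area integrated up to a false positive rate of 10%.

    Focuses on the high-specificity range; when ``normalized`` the value is
    divided by 0.1 so a perfect ranking scores 1.0.
    """
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC0.1 needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    fmax = 0.1
    tpr_at = np.interp(fmax, fpr, tpr)
    keep = fpr < fmax
    fx = np.append(fpr[keep], fmax)
    ty = np.append(tpr[keep], tpr_at)
    area = float(np.trapezoid(ty, fx))
    return area / fmax if normalized else area


# ------------------------------------------------------- expanded-core labels


@dataclass
class ExpandedCoreLabeling:
    labels: np.ndarray  # 1/0 per peptide
    provenance: list[str]  # "core_overlap" | "direct_mapps" | "negative"


def expanded_core_label(
    core_spans: list[tuple[int, int] | None],
    mapps_spans: list[tuple[int, int]],
    protein_length: int | None = None,
    direct_labels: list[bool] | None = None,
) -> ExpandedCoreLabeling:
    """Relaxed positives for benchmarking predictions against MAPPs data.

    A predicted binder is positive when its binding core (1-based inclusive
    protein span) overlaps at least one residue of at least one observed
    MAPPs peptide span.  Peptides without a predicted core (``None``) keep
    their direct MAPPs membership label (default negative).
    """
    for span in mapps_spans:
        if span[0] > span[1]:
            raise ValueError(f"invalid MAPPs span {span}")
    labels = np.zeros(len(core_spans), dtype=int)
    provenance: list[str] = []
    for i, span in enumerate(core_spans):
        if span is None:
            direct = bool(direct_labels[i]) if direct_labels is not None else False
            labels[i] = int(direct)
            provenance.append("direct_mapps" if direct else "negative")
            continue
        s, e = span
        if s > e or s < 1 or (protein_length is not None and e > protein_length):
            raise ValueError(f"core span {span} outside protein")
        hit = any(s <= me and ms <= e for ms, me in mapps_spans)
        labels[i] = int(hit)
        provenance.append("core_overlap" if hit else "negative")
    return ExpandedCoreLabeling(labels=labels, provenance=provenance)


def ppv_top_n(labels, scores) -> float:
    """Positive predictive value among the N top-scoring peptides, N being
    the number of positives.  Ties keep stable input order (logged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos < 1:
        raise ValueError("PPV undefined without positives")
    order = np.argsort(-scores, kind="stable")
    top = order[:n_pos]
    boundary = scores[order[n_pos - 1]]
    if n_pos < len(scores) and scores[order[n_pos]] == boundary:
        logger.info("PPV top-N boundary has tied scores; stable order applied")
    return float(labels[top].sum() / n_pos)


def precision_recall_scan(
    rank_values, labels, thresholds
) -> list[dict[str, float]]:
    """Precision and recall of expanded-core positives at each %Rank
    threshold (a peptide is a predicted binder when %Rank <= threshold)."""
    rank_values = np.asarray(rank_values, dtype=float)
    labels = np.asarray(labels)
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    n_pos = int(labels.sum())
    rows = []
    for t in thresholds:
        pred = rank_values <= t
        tp = int(labels[pred].sum())
        if pred.sum() == 0:
            logger.warning("threshold %g selects no peptides; precision undefined", t)
            precision = float("nan")
        else:
            precision = tp / int(pred.sum())
        recall = tp / n_pos if n_pos else float("nan")
        rows.append(
            {"threshold": float(t), "precision": precision, "recall": recall,
             "n_predicted": int(pred.sum()), "n_true_positive": tp}
        )
    return rows


# ----------------------------------------------------------------- bootstrap


def bootstrap_compare_scc(
    pred_a, pred_b, reference_profile, iters: int = 10_000, seed: int = 0
) -> float:
    """Bootstrap p-value that method A's profile correlation to a reference
    beats method B's.

    Positions are resampled with replacement jointly for all three tracks;
    in each iteration both Spearman correlations are computed.  A "loss" is
    an iteration where the challenger (B) correlates strictly better; ties
    (including undefined correlations on constant resamples) count half, so
    p(A,B) + p(B,A) = 1 and identical methods give p = 0.5.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    ref = np.asarray(reference_profile, dtype=float)
    if not (len(a) == len(b) == len(ref)):
        raise ValueError("tracks must have equal length")
    if iters < 100:
        logger.warning("iters=%d is low for a stable bootstrap p-value", iters)
    rng = np.random.default_rng(seed)
    n = len(ref)
    losses = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(iters):
            idx = rng.integers(0, n, n)
            ra, _ = stats.spearmanr(a[idx], ref[idx])
            rb, _ = stats.spearmanr(b[idx], ref[idx])
            if np.isnan(ra) and np.isnan(rb):
                losses += 0.5
            elif np.isnan(ra):
                losses += 1.0
            elif np.isnan(rb):
                pass
            elif rb > ra:
                losses += 1.0
            elif rb == ra:
                losses += 0.5
    return losses / iters


# ---------------------------------------------------------------------- logos


@dataclass
class LogoMatrix:
    """Kullback-Leibler sequence logo of a 9-residue binding core.

    ``heights[p, a] = p_a * I_p`` with column information content
    ``I_p = sum_a p_a log2(p_a / q_a)``; no sequence weighting is applied.
    """

    heights: np.ndarray  # (9, 20)
    information: np.ndarray  # (9,)
    frequencies: np.ndarray  # (9, 20) pseudocount-smoothed
    background: np.ndarray  # (20,)


def kl_logo(cores: list[str], background_q=None, pseudocount_beta: float = 50.0) -> LogoMatrix:
    """Build a KL logo matrix from aligned 9-mer binding cores.

    Column frequencies are smoothed with ``beta`` background pseudocounts:
    p_a = (count_a + beta*q_a) / (n + beta).
    """
    from .encoding import N_AA, seq_to_indices

    if not cores:
        raise ValueError("empty core set")
    q = (
        np.full(N_AA, 1.0 / N_AA)
        if background_q is None
        else np.asarray(background_q, dtype=float)
    )
    if q.shape != (N_AA,) or not np.isclose(q.sum(), 1.0):
        raise ValueError("background must be a 20-dim probability vector")
    counts = np.zeros((CORE_LEN, N_AA))
    for core in cores:
        if len(core) != CORE_LEN:
            raise ValueError(f"core {core!r} is not {CORE_LEN} residues")
        idx = seq_to_indices(core)
        for p, i in enumerate(idx):
            if i < N_AA:  # wildcards carry no count
                counts[p, i] += 1
    n = len(cores)
    p_mat = (counts + pseudocount_beta * q) / (n + pseudocount_beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_mat > 0, p_mat * np.log2(p_mat / q), 0.0)
    info = terms.sum(axis=1)
    heights = p_mat * info[:, None]
    return LogoMatrix(heights=heights, information=info, frequencies=p_mat, background=q)


# ------------------------------------------------------ amino-acid frequency


def _aa_frequencies(peptides: list[str]) -> np.ndarray:
    from .encoding import N_AA, seq_to_indices

    counts = np.zeros(N_AA)
    for pep in peptides:
        idx = seq_to_indices(pep)
        counts += np.bincount(idx[idx < N_AA], minlength=N_AA)
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable residues in peptide pool")
    return counts / total


def aa_frequency_pcc(
    peptides_a: dict[str, list[str]],
    peptides_b: dict[str, list[str]],
    n_per_allele: int = 500,
    seed: int = 0,
) -> float:
    """Pearson correlation between pooled amino-acid frequency vectors.

    From each source, up to ``n_per_allele`` peptides per allele are sampled
    at random (all of them, with a warning, when fewer exist), pooled, and
    reduced to a 20-dim residue frequency vector.
    """
    rng = np.random.default_rng(seed)

    def pool(source: dict[str, list[str]]) -> list[str]:
        pooled: list[str] = []
        for allele in sorted(source):
            peps = source[allele]
            if not peps:
                continue
            if len(peps) < n_per_allele:
                logger.warning(
                    "allele %s has only %d peptides (< %d); using all",
                    allele, len(peps), n_per_allele,
                )
                pooled.extend(peps)
            else:
                take = rng.choice(len(peps), size=n_per_allele, replace=False)
                pooled.extend(peps[i] for i in take)
        if not pooled:
            raise ValueError("empty peptide pool")
        return pooled

    fa = _aa_frequencies(pool(peptides_a))
    fb = _aa_frequencies(pool(peptides_b))
    r, _ = stats.pearsonr(fa, fb)
    return float(r)


# -------------------------------------------------------------------- elispot


def elispot_call(
    peptide_replicates, control_values, n_sd: float = 4.0
) -> tuple[float, bool]:
    """T cell activation call from ELISpot spot-forming-unit counts.

    Returns (delta SFU, positive?) where delta SFU is the mean peptide signal
    minus the mean unstimulated (medium) control, and the response is called
    positive only when every independent peptide replicate exceeds the
    control mean by at least ``n_sd`` sample standard deviations.
    """
    reps = np.asarray(peptide_replicates, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if len(reps) < 2:
        raise ValueError("need at least 2 peptide replicates")
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control values")
    delta = float(reps.mean() - ctrl.mean())
    threshold = ctrl.mean() + n_sd * ctrl.std(ddof=1)
    return delta, bool(np.all(reps >= threshold))
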