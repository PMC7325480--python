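# Methods

This note documents the model, the training procedure, the synthetic study
conditions, the numerical choices, and what the tests do and do not
demonstrate.

## Model

The predictor is a single-hidden-layer network with hard binding-core
alignment. For a peptide of length L (9 ≤ L, training data restricted to
13–21) and an allele represented by its 34-residue pseudo-sequence, every
core offset `o ∈ {0..L−9}` yields a 1111-dimensional input:

| block | dims | encoding |
|---|---|---|
| binding core | 9×20 | BLOSUM62 row of each residue, scaled by 1/5 |
| flank lengths | 2 | min(left,3)/3, min(right,3)/3 |
| peptide length | 9 | one-hot over 13–21, clamped outside |
| context (PCI) | 12×20 | 3 upstream + first 3 + last 3 + 3 downstream residues |
| pseudo-sequence | 34×20 | BLOSUM62 rows |

The wildcard X (and absent context, as in binding-affinity assays) encodes
as zeros. Output and hidden activations are logistic; the peptide score is
the maximum over offsets, and the argmax offset is the predicted core
(ties → smallest offset). Mixed targets: transformed affinities
`t = clip(1 − log IC50 / log 50000, 0, 1)` and eluted-ligand 1/0 labels,
under a squared-error loss.

## Training

Stochastic gradient descent in mini-batches of 32 with the *summed* batch
gradient, so the default learning rate 0.05 has the per-example semantics of
online SGD. The gradient flows only through the max-scoring core, recomputed
at every presentation.

**Alignment burn-in.** For the first `burnin_epochs` (default 25) epochs the
core is pinned to the central window instead of the argmax. Free alignment
from a random initialization is register-unstable: the motif can settle a
fixed 1–3 positions away from the true core frame, which leaves
discrimination intact but makes recovered motifs incomparable to any
reference frame. Pinning early training to the ligand centre (where MHC-II
cores concentrate, flanks being trimmed roughly symmetrically) breaks the
shift symmetry; the remaining epochs refine placements freely.

**Two-step multi-allele training.** Pre-training runs `epochs_pretrain`
(default 20) epochs on single-allele data only. Each subsequent cycle
(up to `epochs_total`, 400 at full scale, 40 at desk scale) annotates every
multi-allele positive with the donor allele scoring it highest, then trains
one epoch on SA plus annotated MA data, then re-annotates. Two details
matter:

* *Rank-normalized annotation.* Raw scores are not comparable across
  alleles; argmax on raw scores collapses within a few cycles to a single
  allele absorbing every ligand. The training loop therefore converts each
  allele's scores to percentiles against a fixed 2,000-peptide subsample of
  the augmented negatives (which are random flat-length background peptides)
  before taking the argmax. The public `annotate_ma` defaults to raw-score
  argmax and accepts an optional rank reference.
* *Negatives get random alleles each cycle*, spreading the negative signal
  instead of systematically punishing the currently best motif.

The ensemble is the full grid of initialization seeds × hidden sizes
{20, 40, 60} × 5 cross-validation folds (150 networks at full
scale; the desk-scale default is 1 seed × 40 hidden × 5 folds). Partitions
come from Hobohm-style common-motif clustering: peptides sharing any
identical 9-mer are merged transitively, and whole clusters are assigned
largest-first to the smallest partition, so no 9-mer crosses folds.
Cross-validated metrics only ever use members whose held-out fold contains
the peptide.

## Rank calibration and profiles

Per allele, scores of `n_random` background peptides (flat lengths 13–21,
drawn from a background proteome with their true context; 10⁵ at full scale)
define the empirical %Rank: the percentage of background scoring at least as
high, ties counted conservatively, floored at 100/n. %Rank is monotone
non-increasing in score by construction.

A protein is profiled by digesting it into all overlapping 13–21-mers
(Σ_ℓ (P−ℓ+1) windows, X-padded context at the termini). MAPPs profiles stack
per-donor-deduplicated experimental peptides of ≥12 residues over the
sequence; promiscuity profiles keep per allele the windows below a %Rank
threshold, mark covered positions at most once per allele, and sum across
alleles. Both are max-normalized to 1.

**Threshold for dense digests.** On real antibodies a 1%Rank cut is the
benchmark optimum. In a full digest, however, ~135 windows overlap each
position, so the expected number of selected background windows per position
at threshold τ% is ≈1.35τ; at τ=1 background coverage saturates and the
profile loses contrast. The synthetic hotspot workflow therefore uses
τ=0.25 (expected ≈0.34 background selections per position). Users profiling
real proteins should scan τ as the evaluation module's precision–recall scan
supports.

## Evaluation stack

Spearman correlation between per-position tracks (NaN with a warning for
constant tracks); AUC0.1 (ROC area to FPR 0.1, reported normalized so a
perfect ranking is 1.0, computed without dropped intermediate thresholds so
it matches an exhaustive sweep exactly); expanded-core labelling (a
predicted binder is a relaxed positive when its core span shares ≥1 residue
with an observed ligand span); PPV among the top-N (N = number of
positives, stable tie order); precision–recall over %Rank thresholds;
bootstrap comparison of two profiles against a reference (joint resampling
of positions, p = (losses + ties/2)/iterations, so p(A,B)+p(B,A)=1 and
identical methods give 0.5); Kullback–Leibler logos without sequence
weighting (column frequencies smoothed by β=50 background pseudocounts,
heights p·I with I = Σ p log₂(p/q)); pooled amino-acid frequency Pearson
correlation (500 peptides per allele by default); and the ELISpot call
(ΔSFU = mean(peptide) − mean(medium); positive only when every replicate
exceeds the control mean by 4 sample standard deviations).

## Synthetic study conditions

The generator emulates the statistical structure of the real training data,
not its biology:

* **Motifs**: 9×20 position-probability matrices with anchors at core
  positions {1,4,6,9}; anchor columns put weight c/(c+1) (c = 5 by default,
  ≈0.83) on a preferred residue, non-anchor columns are Dirichlet draws
  around the flat background. Motif *sets* draw anchor preferences without
  replacement across alleles and distinct within each motif: shared anchors
  make deconvolution unidentifiable (label switching), repeated within-motif
  anchors make the motif self-similar under shifts and its register
  ambiguous.
* **Ligands**: lengths from an asymmetric triangular distribution peaked at
  15 (modal fraction 0.2) over 13–21; cores embedded at a centred binomial
  offset, mirroring symmetric exoprotease trimming of MHC-II flanks —
  uniform placement leaves the core register unidentifiable.
* **Donors**: allele usage ~90% on DRB1-like names (0.45/0.45/0.05/0.05 for
  the default four-allele genotype); negatives added per the augmentation
  rule (5× the modal positive length count per length bin, ≈9–10 negatives
  per positive at the default length shape).
* **Affinity data**: targets are a logistic squashing of standardized motif
  log-odds plus Gaussian noise (σ=0.1), half the peptides carrying a planted
  core; 1,000 records per allele at desk scale, commensurate with public
  single-allele sets for common DRB1 alleles.
* **Pseudo-sequences**: 10-substitution variants of one shared 34-mer
  scaffold, deterministic per allele name — pairwise distinct but similar,
  as real class II groove residues are; pan-specific transfer between
  alleles relies on that similarity.
* **Protein drugs**: random backbone with non-overlapping planted 9-mer
  cores sampled from the motif set; planted intervals are the ground-truth
  hotspots.

The desk-scale study (two donors × four alleles, 500 positives each, five
networks, 40 cycles) runs in ~2 minutes on one CPU and recovers
deconvolution accuracy ≥0.94 and motif PCC ≥0.96 at the fixed default seed.

What passing these tests shows: the estimator recovers planted structure
under the stated conditions — separable anchor motifs, clean labels, a
uniform-composition background. What it does not show: performance on real
immunopeptidomes, whose motifs overlap between alleles, whose negatives are
contaminated with true binders, whose length/cleavage biases are
instrument-dependent, and whose allele usage varies by donor. Numbers
reported on real data in the literature are not reproducible from this
package without the original datasets.

## Numerical choices and degenerate inputs

* Weight initialization uniform ±0.05 from the per-network seed; training is
  bit-reproducible given (seed, data).
* Offset ties break to the smallest offset; annotation ties to the donor's
  first-listed allele; top-N ties keep stable input order and are logged.
* Constant profiles → NaN correlations with warnings rather than errors;
  empty digests (protein shorter than 13) warn and return empty.
* %Rank of a score above all background is 100/n, never 0.
* Lengths outside 13–21 at prediction time clamp to the nearest length bin
  rather than failing.
* The rank-normalization subsample during training is capped at 2,000
  negatives — percentile resolution 0.05%, finer than any annotation margin
  that matters at desk scale.

## Known limitations

* Rare alleles (few eluted ligands in every donor) depend on the
  single-allele data for their register; at some generator seeds their
  recovered motif can still land a position off frame. Abundant alleles are
  stable across seeds.
* The desk-scale ensemble (5 networks) leaves each fold to a single
  network, so cross-validated AUC0.1 is noisier than the full 150-network
  grid would give.
* Hard-argmax training admits no uncertainty over cores; peptides whose
  true core is off-centre by more than the burn-in tolerance are aligned
  only after burn-in ends.
* The CLI trains donors whose genotypes are listed in one table and assumes
  all alleles appear in the pseudo-sequence table; mixed pseudo-sequence
  lengths are rejected rather than padded.
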