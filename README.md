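# mhc2deconv

Pan-specific MHC class II antigen-presentation prediction with multi-allele
immunopeptidome deconvolution and protein-drug hotspot profiling.

## The problem

MHC class II molecules present 13–21-residue peptides to CD4 T cells; which
peptides of a protein therapeutic get presented largely determines its
immunogenicity risk. Eluted-ligand mass spectrometry (MAPPs) reads out the
presented peptidome of a donor's dendritic cells, but each donor expresses
several HLA class II alleles at once, so the restricting allele of every
ligand — and the 9-mer binding core seated in the groove — is unobserved.
`mhc2deconv` is for immunoinformaticians who want to train presentation
predictors from such multi-allele (MA) data together with single-allele (SA)
binding-affinity measurements, and to turn the trained model into per-residue
presentation-hotspot profiles of a protein drug.

## The model

A shallow feed-forward network scores a peptide `p` for an allele `a` by
evaluating every placement of the 9-mer core and keeping the best
(NNAlign-style hard alignment):

```
score(p, a) = max_{offset} σ( w2 · σ(W1 x(p, a, offset) + b1) + b2 )
```

The input `x` concatenates BLOSUM-encoded core residues, peptide-flanking
lengths, a peptide-length one-hot (13–21), 12 residues of peptide context
(PCI: peptide termini plus source-protein flanks), and the allele's 34-residue
MHC pseudo-sequence — the pan-specific representation that lets one network
serve all alleles (1111 inputs in total). Training targets mix transformed
binding affinities, `t = 1 − log(IC50)/log(50000)`, with eluted-ligand 1/0
labels.

Training is the two-step multi-allele scheme: networks pre-train on SA data,
then alternate between (i) annotating each MA ligand with the donor allele
whose (rank-normalized) score is highest and (ii) one training epoch on SA
plus annotated MA data, for up to 400 cycles. An ensemble over initialization
seeds × hidden-layer sizes {20, 40, 60} × 5 Hobohm common-motif
cross-validation partitions (150 networks at full scale) is averaged for
predictions. Scores are calibrated to %Rank against 10⁵ random background
peptides per allele; a protein is profiled by digesting it into all
overlapping 13–21-mers, keeping per-allele top-ranked peptides, capping
coverage at one per allele per position and summing across alleles — the
"promiscuity" profile of presentation hotspots.

Because the original mass-spectrometry and IEDB training data cannot ship
with the package, a first-class synthetic-data module generates
ground-truthed stand-ins: per-allele anchor motifs, peaked length
distributions, ~90% DRB1-skewed donor mixtures, affinity data correlated with
motif score, and protein drugs with planted binder regions.

## Worked example

```python
from mhc2deconv.workflows import run_parameter_recovery, run_hotspot_check
from mhc2deconv.trainer import cross_validate

study = run_parameter_recovery(seed=1)        # ~2 minutes on one CPU
print(study.deconvolution_accuracy)
print({k: round(v, 3) for k, v in study.motif_pcc.items()})
print({k: round(v, 3) for k, v in cross_validate(study.ensemble, study.donors).items()})
profile, truth, flags = run_hotspot_check(study, seed=1)
print(truth.regions, flags)
```

prints (seed 1):

```
{'D0': 0.958, 'D1': 0.968}
{'DRB1_A': 0.998, 'DRB1_B': 0.997, 'DRB3_C': 0.966, 'DRB5_D': 0.96}
{'D0': 0.83, 'D1': 0.822}
[(23, 31), (83, 91), (133, 141), (150, 158)] [True, True, True, True]
```

Reading this: two synthetic donors, each expressing four alleles with ~90% of
ligands from the two DRB1-like alleles, are deconvoluted so that ~96% of
ligands are re-assigned to the allele that actually generated them; the motif
recovered from each allele's assigned cores correlates at PCC ≥ 0.96 with the
planted position-probability matrix; held-out cross-validated AUC0.1 is ~0.83
per donor; and all four binder regions planted in a synthetic protein drug
rise above the median of its promiscuity profile.

The same stages are scriptable from the shell:

```bash
mhc2deconv simulate --out data --seed 1
mhc2deconv train --data data --out model --seed 1
mhc2deconv predict --model model --peptides data/sa.tsv \
    --background data/background_proteome.fasta --out predictions.tsv
mhc2deconv profile --model model --protein drug.fasta \
    --background data/background_proteome.fasta --out profile.tsv
```

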