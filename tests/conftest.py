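import numpy as np
import pytest

from mhc2deconv import simulate as sim
from mhc2deconv.datamodel import AlleleSpec, PeptideRecord


@pytest.fixture(scope="session")
def proteome():
    return sim.random_proteome(42, n_proteins=10, length=400)


@pytest.fixture(scope="session")
def motif():
    return sim.generate_motif(3, allele="DRB1_T")


@pytest.fixture(scope="session")
def allele_spec():
    return AlleleSpec(name="DRB1_T", pseudo_sequence=sim.pseudo_sequence_for("DRB1_T"))


def make_peptide(seq: str, kind: str = "EL_positive", **kw) -> PeptideRecord:
    target = kw.pop("target", 1.0 if kind == "EL_positive" else 0.0)
    return PeptideRecord(sequence=seq, source_kind=kind, target=target, **kw)


@pytest.fixture(scope="session")
def random_peptides(proteome):
    """120 random proteome 13-21mers with context."""
    from mhc2deconv.profiles import sample_background_peptides

    return sample_background_peptides(proteome, 120, seed=7)


@pytest.fixture(scope="session")
def trained_single_net(motif, allele_spec, proteome):
    """One small network trained on synthetic single-allele data (seconds)."""
    from mhc2deconv.encoding import PackedPeptides, encode_pseudo
    from mhc2deconv.network import Network, NetworkConfig

    sa = sim.generate_sa_ba(motif, 500, noise_sd=0.1, seed=2, proteome=proteome)
    packed = PackedPeptides(sa)
    pseudo = np.stack([encode_pseudo(allele_spec)])
    idx = np.zeros(packed.n, dtype=np.int64)
    net = Network(NetworkConfig(hidden_units=20, seed=3))
    rng = np.random.default_rng(0)
    for epoch in range(30):
        net.train_epoch(packed, pseudo, idx, rng, center_core=epoch < 10)
    return net


@pytest.fixture(scope="session")
def study():
    """The desk-scale parameter-recovery study (the expensive fixture:
    trains the five-network cross-validated ensemble end to end)."""
    from mhc2deconv.workflows import run_parameter_recovery

    return run_parameter_recovery(seed=1)
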