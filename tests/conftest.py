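import numpy as np
import pytest

from cerna_weaver.synthgen import SynthConfig, gen_transcriptome
from cerna_weaver.targetpred import PredictParams, predict

#: Reference synthetic-study conditions: 20 miRNAs, 100 mRNAs, one planted
#: site per UTR, seed 42.
REFERENCE_CONFIG = SynthConfig(
    n_mirna=20, n_mrna=100, n_pseudogene=10, planted_sites_per_utr=1, rng_seed=42
)

ALL_ELEMENTS = ("MBE", "GAIT", "CPE", "ARE", "MOS-PRE", "GU-rich", "UNR")


@pytest.fixture(scope="session")
def ref_bundle():
    """Reference transcriptome bundle (transcripts, mirnas, truth)."""
    return gen_transcriptome(REFERENCE_CONFIG)


@pytest.fixture(scope="session")
def ref_predictions(ref_bundle):
    """Target predictions on the reference bundle's mRNAs at default parameters."""
    transcripts, mirnas, truth = ref_bundle
    mrnas = [t for t in transcripts if t.biotype == "protein_coding"]
    interactions, stats = predict(mirnas, mrnas, PredictParams(som_seed=42))
    return interactions, stats


@pytest.fixture(scope="session")
def element_bundle():
    """Bundle with every cis-element class planted in each of 100 UTRs."""
    cfg = SynthConfig(
        n_mirna=10,
        n_mrna=100,
        n_pseudogene=0,
        utr_len_range=(150, 300),
        planted_elements=ALL_ELEMENTS,
        rng_seed=7,
    )
    return gen_transcriptome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
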