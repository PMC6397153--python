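import numpy as np
import pytest

from clairlite import simdata


@pytest.fixture(scope="session")
def small_sim():
    """A 6-kb noisy diploid fixture (SMS-like errors, depth 20)."""
    ref = simdata.make_reference(6000, seed=21)
    truth = simdata.plant_variants(ref, 30, 8, 8, seed=22)
    reads, ledger = simdata.simulate_reads(truth, 20, simdata.SMS, seed=23)
    return {"chrom": "ctg1", "ref": ref, "truth": truth, "reads": reads,
            "ledger": ledger}


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free reads over planted variants (2-bp indels only)."""
    profile = simdata.ErrorProfile(0.0, 0.0, 0.0, 400, "clean")
    ref = simdata.make_reference(4000, seed=31)
    truth = simdata.plant_variants(ref, 8, 5, 5, seed=32,
                                   indel_length_weights={2: 1.0})
    reads, ledger = simdata.simulate_reads(truth, 15, profile, seed=33)
    return {"chrom": "ctg1", "ref": ref, "truth": truth, "reads": reads,
            "ledger": ledger, "profile": profile}


@pytest.fixture(scope="session")
def homref_sim():
    """Noisy reads over a variant-free genome (pure error background)."""
    ref = simdata.make_reference(5000, seed=41)
    truth = simdata.plant_variants(ref, 0, 0, 0, seed=42)
    reads, ledger = simdata.simulate_reads(truth, 25, simdata.SMS, seed=43)
    return {"chrom": "ctg1", "ref": ref, "truth": truth, "reads": reads,
            "ledger": ledger}
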