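import numpy as np
import pytest

from gravqtl import curves, qtl, simdata


@pytest.fixture(scope="session")
def ten_chrom_cross():
    """Simulated 10-chromosome RIL cross used across mapping tests."""
    gmap = simdata.simulate_genetic_map([(str(c), 100.0) for c in range(1, 11)], 5.0)
    geno = simdata.simulate_ril_genotypes(gmap, 200, seed=42)
    probs = qtl.calc_genoprob(geno, gmap, step_cM=1.0)
    return gmap, geno, probs


@pytest.fixture(scope="session")
def gravitropism_stack():
    """Zero-noise 61-frame synthetic root image stack with known angles."""
    t = np.arange(0.0, 181.0, 3.0)
    traj = curves.logistic(t, 85.0, 0.9, 20.0)
    stack, truth = simdata.simulate_root_image_series(traj, noise_sd=0.0)
    return stack, truth
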