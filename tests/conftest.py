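import numpy as np
import pytest

from perfstab.phantom import PhantomScan, PhantomSpec, build_phantom, simulate_ctp_series, simulate_ncct


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def noisy_scan(default_spec, default_truth):
    """One simulated CTP + NCCT acquisition at default noise."""
    rng = np.random.default_rng(7)
    ctp = simulate_ctp_series(default_truth, default_spec, rng=rng)
    ncct = simulate_ncct(
        default_truth,
        default_spec.core_hypodensity_hu,
        default_spec.ncct_noise_sd,
        rng=rng,
    )
    return PhantomScan(ctp, ncct, "080000.000000", default_truth.affine.copy())


@pytest.fixture(scope="session")
def noisefree_scan(default_truth):
    """Same anatomy simulated without noise (for exact-recovery checks)."""
    from dataclasses import replace

    spec = replace(PhantomSpec(seed=7), noise_sd=0.0)
    ctp = simulate_ctp_series(default_truth, spec, rng=np.random.default_rng(0))
    ncct = simulate_ncct(default_truth, spec.core_hypodensity_hu, 0.0)
    return PhantomScan(ctp, ncct, "080000.000000", default_truth.affine.copy())


@pytest.fixture(scope="session")
def default_analysis(noisy_scan, default_truth):
    from perfstab.pipeline import analyze_scan

    return analyze_scan(
        noisy_scan, default_truth.atlas_labels, default_truth.region_names
    )


def dice(a, b) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
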