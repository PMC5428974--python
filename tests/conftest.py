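import numpy as np
import pytest

from autozyg.roh_mapping import CallClass, ROHInterval, ROHParams
from autozyg.synthetic_pedigree import SimConfig, build_first_cousin_pedigree, emit_vcf, simulate_family


@pytest.fixture(scope="session")
def first_cousin_pedigree():
    return build_first_cousin_pedigree()


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One deterministic segregating replicate, emitted to disk."""
    config = SimConfig(random_seed=11)
    pedigree, truth = simulate_family(config)
    out = tmp_path_factory.mktemp("sim")
    paths = emit_vcf(truth, config, out)
    return config, pedigree, truth, paths


def random_classified_sites(rng: np.random.Generator, max_sites: int = 200):
    """Random (position, CallClass) chromosome for oracle comparisons."""
    n = int(rng.integers(0, max_sites + 1))
    positions = np.sort(rng.choice(10 * max_sites, size=n, replace=False))
    classes = rng.choice(
        np.array(
            [CallClass.HQ_HOM, CallClass.HET, CallClass.LOW_QUALITY, CallClass.MISSING]
        ),
        size=n,
        p=[0.6, 0.2, 0.1, 0.1],
    )
    return [(int(p), c) for p, c in zip(positions, classes)]


def brute_force_roh(sites, params: ROHParams, chromosome="1", sample_id="sample"):
    """Independent ROH oracle: test every candidate window of supporting SNVs
    directly against the rule (>= min_run consecutive high-quality homozygous
    SNVs, no heterozygote strictly inside, not extendable on either side)."""
    from bisect import bisect_left, bisect_right

    homs = [p for p, c in sites if c is CallClass.HQ_HOM]
    hets = sorted(p for p, c in sites if c is CallClass.HET)

    def het_between(a, b):
        return bisect_left(hets, b) > bisect_right(hets, a)

    out = []
    for i in range(len(homs)):
        for j in range(i + params.min_run - 1, len(homs)):
            if het_between(homs[i], homs[j]):
                continue
            left_maximal = i == 0 or het_between(homs[i - 1], homs[i])
            right_maximal = j == len(homs) - 1 or het_between(homs[j], homs[j + 1])
            if left_maximal and right_maximal:
                out.append(
                    ROHInterval(
                        chromosome=chromosome,
                        start=homs[i],
                        end=homs[j] + 1,
                        n_snvs=j - i + 1,
                        sample_id=sample_id,
                    )
                )
    return out
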