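#!/usr/bin/env python
"""Simulate the index-style consanguineous family.

Gene-drops a first-cousin pedigree (two affected boys, expected inbreeding
F = 1/16) until the planted loss-of-function variant segregates, then emits
VCF + PED + annotation TSV + truth JSON under results/sim/.
"""

from pathlib import Path

from autozyg.synthetic_pedigree import AFFECTED_CHILDREN, SimConfig, emit_vcf, simulate_family

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17


def main() -> None:
    config = SimConfig(random_seed=SEED)
    pedigree, truth = simulate_family(config)
    paths = emit_vcf(truth, config, RESULTS / "sim")
    lengths = {c: config.chromosome_length(c) for c in config.autosomes}

    print(f"pedigree: {len(pedigree.members)} members, "
          f"{len(pedigree.affected)} affected; parents' kinship = "
          f"{pedigree.kinship('F', 'M'):.4f}")
    print(f"replicate segregates after {truth.n_resamples} resamples")
    for child in AFFECTED_CHILDREN:
        frac = truth.autozygous_fraction(child, lengths)
        print(f"{child}: autozygous fraction {frac:.4f} (expectation 0.0625)")
    for chrom, segs in truth.shared_autozygous_segments.items():
        for s, e, label in segs:
            print(f"shared autozygous segment: chr{chrom}:{s:,}-{e:,} "
                  f"({(e - s) / 1e6:.2f} Mb, founder haplotype {label})")
    print(f"planted variant: chr{truth.variant_positions['planted_lof'][0]}:"
          f"{truth.variant_positions['planted_lof'][1]:,} "
          f"genotypes {truth.variant_genotypes['planted_lof']}")
    for key, path in paths.items():
        print(f"wrote {key}: {path}")


if __name__ == "__main__":
    main()
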