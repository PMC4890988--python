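#!/usr/bin/env python
"""Generate the synthetic study bundle the downstream analyses consume.

Emits a complete case-control GWAS arm (PLINK text genotypes + phased VCF
LD panel + BED gene annotation), a two-group expression matrix, a pathway
collection (GMT) and the planted ground truth, all under results/study/.
"""

import sys

import pathfuse as pf
from pathfuse.experiments import RECOVERY_CONFIG

OUTDIR = "results/study"


def main() -> int:
    cfg = pf.SimulationConfig(seed=1, **RECOVERY_CONFIG)
    bundle = pf.simulate_all(cfg)
    manifest = pf.write_fixture_bundle(OUTDIR, bundle)
    t = bundle.truth
    print(f"wrote {len(manifest)} files to {OUTDIR}/")
    print(f"  genes: {len(bundle.annotation)}  SNPs: {bundle.genotypes.n_snps}")
    print(f"  samples: {bundle.genotypes.n_samples} genotyped, "
          f"{bundle.expression.values.shape[1]} arrays")
    print(f"  planted: {len(t.causal_gene_ids)} causal genes, "
          f"{len(t.de_gene_ids)} DE genes, "
          f"{len(t.enriched_pathway_ids)} enriched pathways "
          f"({sorted(t.enriched_pathway_ids)})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
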