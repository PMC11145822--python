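#!/usr/bin/env python
"""Generate the synthetic three-lipid / AMI study and write its input files.

Emulates the shape of the real data sources (a GLGC-style lipid GWAS for
LDL-C, HDL-C and TG; a UK-Biobank-style binary outcome with ~1.2% cases) and
writes tab-delimited summary statistics, an LD matrix, a gene-region table
and a confounder lookup under results/data/, plus the generator's ground
truth for later comparison.
"""

import argparse
import json
from pathlib import Path

from mrlipid.gwas_io import write_summary_stats
from mrlipid.instruments import write_ld_matrix
from mrlipid.synthetic import paper_like_config, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    outdir = ROOT / "results" / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_dataset(paper_like_config(), seed=args.seed)

    for name, records in study.exposures.items():
        write_summary_stats(records, outdir / f"exposure_{name}.tsv")
    write_summary_stats(study.outcome, outdir / "outcome_AMI.tsv")
    write_ld_matrix(study.ld, outdir / "ld_matrix.tsv")
    with open(outdir / "gene_regions.tsv", "w") as fh:
        for region in study.regions:
            fh.write(f"{region.gene}\t{region.chrom}\t{region.start}\t{region.end}\n")
    with open(outdir / "confounders.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in study.confounders.items()}, fh,
                  indent=2, sort_keys=True)
    truth = {
        "theta_per_unit": list(study.truth.theta),
        "region_theta": study.truth.region_theta,
        "n_snps_total": len(study.truth.snp_ids),
        "n_outliers": len(study.truth.outlier_ids),
        "seed": args.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    n = len(study.outcome)
    print(f"wrote {n} SNPs x (3 exposures + outcome) to {outdir}")
    print(f"planted causal effects per unit of exposure: {truth['theta_per_unit']}")
    print(f"cis regions: {[r.gene for r in study.regions]}")


if __name__ == "__main__":
    main()
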