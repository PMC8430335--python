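#!/usr/bin/env python
"""Genome recovery by composition+coverage binning, with the marker tally
and fragment ANI.

Sixty 20-kb contigs from three genomes (GC 0.30/0.50/0.70, coverage
5/20/80 across three pseudo-samples) are clustered on tetranucleotide
PCA + GC + log RPKG; bins are scored against the planted genomes
(adjusted Rand index) and by the single-copy marker tally. A self-ANI
and a 5%-mutated-reference ANI calibrate the fragment aligner.
Writes results/bins.tsv and results/ani.tsv.
"""

from pathlib import Path

import pandas as pd

from lrmine.experiments import ani_experiment, binning_recovery

SEED = 20210827


def main() -> None:
    res = binning_recovery(SEED)
    Path("results").mkdir(exist_ok=True)
    rows = [
        {
            "bin_id": b.bin_id,
            "n_contigs": len(b.contig_ids),
            "completeness": b.completeness,
            "contamination": b.contamination,
            "quality": b.quality,
        }
        for b in res["bins"]
    ]
    pd.DataFrame(rows).to_csv("results/bins.tsv", sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"\nadjusted Rand index vs planted genomes: {res['ari']:.3f} "
          f"({res['n_bins']} bins over {res['n_contigs']} contigs)")

    ani_res = ani_experiment(SEED)
    ani_rows = [
        {"comparison": "self", "ani": ani_res["self"].ani,
         "fragments": ani_res["self"].n_fragments_used},
        {"comparison": "5pct_mutated_reference", "ani": ani_res["mutated"].ani,
         "fragments": ani_res["mutated"].n_fragments_used},
    ]
    pd.DataFrame(ani_rows).to_csv("results/ani.tsv", sep="\t", index=False)
    print(f"ANI self {ani_res['self'].ani:.2f}%, "
          f"5%-mutated reference {ani_res['mutated'].ani:.2f}%")


if __name__ == "__main__":
    main()
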