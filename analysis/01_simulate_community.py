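#!/usr/bin/env python
"""Generate the demonstration community used by the downstream drivers.

Three genomes (GC 0.38/0.48/0.58) carry planted GT clusters, CRISPR
arrays whose spacers are copied from the emitted virome, rhodopsin genes
and 10 single-copy markers each. CCS-like long reads are simulated at
5, 10 and 15 passes (1%, 0.1%, 0.05% error), plus 2x100 bp short reads.
Everything lands under results/community/.
"""

from pathlib import Path

from lrmine.experiments import feature_community
from lrmine.io_core import write_fastq
from lrmine.synthetic_community import (
    ErrorModel,
    simulate_long_reads,
    simulate_short_reads,
    save_community,
    write_provenance_tsv,
)

SEED = 20210827
OUT = Path("results/community")


def main() -> None:
    truth = feature_community(SEED)
    save_community(truth, OUT)
    model = ErrorModel()
    for passes in (5, 10, 15):
        reads = simulate_long_reads(
            truth, model, n_reads=600, passes=passes,
            seed=SEED + passes, id_prefix=f"ccs{passes}",
        )
        write_fastq(reads, OUT / f"reads_ccs{passes}.fastq")
        print(f"CCS{passes}: {len(reads)} reads at {model.per_pass_table[passes]:.2%} error")
    r1, r2 = simulate_short_reads(truth, error_rate=0.001, n_pairs=2000, seed=SEED + 99)
    write_fastq(r1, OUT / "short_R1.fastq")
    write_fastq(r2, OUT / "short_R2.fastq")
    write_provenance_tsv(truth, OUT / "provenance.tsv")
    print(f"community: {len(truth.records)} genomes, {len(truth.virome)} virome "
          f"sequences, {len(truth.features)} planted features -> {OUT}")


if __name__ == "__main__":
    main()
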