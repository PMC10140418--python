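#!/usr/bin/env python
"""Generate the synthetic aging study all downstream analyses consume.

Emulates a four-age mouse brain small-RNA design (postnatal days 22, 40,
60, 120; 8 samples per age): 100 miRNAs of which 30% undergo true 3'
shortening at 0.01-0.02 nt/day (half via trimming, half via U-tail
decline), 300 mRNA targets with programmed age trends, constant-
expectation spike-ins, and an interaction table from three nominal
prediction tools.  Writes the same TSV formats the readers consume plus
ground-truth tables under results/synthetic_study/.
"""

from pathlib import Path

from era3 import SimulationConfig, simulate_expression, simulate_isomir_table
from era3 import io as eio
from era3.expression import write_expression_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"
SEED = 20240


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, n_mirnas=100, n_targets=300,
                           n_interactions=800, link_strength=0.9)
    table, metadata, truth = simulate_isomir_table(cfg)
    matrix, interactions, truth = simulate_expression(cfg, truth, metadata)

    eio.write_isomir_table(table, OUT / "isomirs.tsv")
    eio.write_catalog(table.catalog, OUT / "catalog.fa")
    metadata.to_csv(OUT / "metadata.tsv", sep="\t")
    write_expression_matrix(matrix, OUT / "counts.tsv", OUT / "feature_classes.tsv")
    long = interactions.pairs.explode("sources").rename(columns={"sources": "source"})
    long[["mirna_id", "target_id", "source"]].to_csv(
        OUT / "interactions.tsv", sep="\t", index=False
    )
    truth.mirnas.to_csv(OUT / "truth_mirnas.tsv", sep="\t", index=False)
    truth.targets.to_csv(OUT / "truth_targets.tsv", sep="\t", index=False)
    truth.pairs.assign(
        sources=truth.pairs["sources"].map(lambda s: ";".join(sorted(s)))
    ).to_csv(OUT / "truth_pairs.tsv", sep="\t", index=False)

    n_short = int(truth.mirnas["shortened"].sum())
    print(f"wrote synthetic study to {OUT}")
    print(f"  {len(table.records)} isomiR records, {cfg.n_mirnas} miRNAs "
          f"({n_short} truly shortened), {len(metadata)} samples")
    print(f"  expression matrix: {matrix.counts.shape[0]} features "
          f"({cfg.n_targets} mRNA targets, "
          f"{cfg.spikein_small_n + cfg.spikein_large_n} spike-ins)")
    print(f"  {len(interactions)} predicted interactions, "
          f"{int(truth.pairs['linked'].sum())} with imposed correlation links")


if __name__ == "__main__":
    main()
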