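#!/usr/bin/env python
"""Score the simulated gene-trap screen and check planted-effect recovery.

Reads the HIGH/LOW pools and gene models from 01, computes per-gene
mutational indices with Fisher/BH hit calling, writes
results/screen_scores.tsv, and reports sensitivity and false-discovery
rate against the planted truth.
"""

from pathlib import Path

import pandas as pd

from ladscreen import formats_io as fio
from ladscreen import screen_stats as ss

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    models = fio.read_gene_models(data / "gene_models.tsv")
    regions = ss.build_counting_regions(models)
    high = ss.dedupe_pool(fio.read_insertions(data / "pool_high.bed", "HIGH"), "HIGH")
    low = ss.dedupe_pool(fio.read_insertions(data / "pool_low.bed", "LOW"), "LOW")

    scores = ss.score_screen(high, low, regions)
    scores.to_csv(ROOT / "screen_scores.tsv", sep="\t", index=False)

    truth = pd.read_csv(data / "screen_truth.tsv", sep="\t")
    planted = set(truth.loc[truth["class"] != "neutral", "gene_id"])
    hits = scores[scores["fcpv"] < 0.05]
    tp = hits[hits["gene_id"].isin(planted)]
    print(f"{len(scores)} genes tested; {len(hits)} hits at fcpv < 0.05 "
          f"({(hits['hit_class'] == 'repressor').sum()} repressors, "
          f"{(hits['hit_class'] == 'activator').sum()} activators)")
    print(f"recovery of 100 planted effects: sensitivity "
          f"{len(tp) / len(planted):.2f}, FDR {1 - len(tp) / max(len(hits), 1):.3f}")


if __name__ == "__main__":
    main()
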