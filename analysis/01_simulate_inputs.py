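#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/: a gene-model table, HIGH/LOW gene-trap
insertion pools (with 50 planted repressors and 50 planted activators),
a DamID-style NL-contact track with planted LADs, an RNA-seq count matrix
with LAD-biased planted responses, and a TRIP barcode count table with a
planted knockdown effect — plus the ground-truth tables for each.
"""

from pathlib import Path

from ladscreen import formats_io as fio
from ladscreen import synthetic_data as sd
from ladscreen.benchmarks import planted_theta

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    layout, models = sd.synthetic_gene_models(n_genes=2_000, seed=sd.rng_for(SEED, "genome"))
    fio.write_gene_models(OUT / "gene_models.tsv", models)

    cfg = sd.ScreenSimConfig(theta=planted_theta(models, 50, 50), seed=SEED)
    high, low, truth = sd.simulate_screen(cfg, models, layout)
    fio.write_insertions(OUT / "pool_high.bed", high.as_insertions())
    fio.write_insertions(OUT / "pool_low.bed", low.as_insertions())
    truth.to_csv(OUT / "screen_truth.tsv", sep="\t", index=False)
    print(f"screen: {high.size} HIGH / {low.size} LOW unique insertions, "
          f"{len(models)} genes (50 planted repressors, 50 activators)")

    lads = sd.synthetic_lads(layout, seed=sd.rng_for(SEED, "lads"))
    track, lads = sd.simulate_damid_track(sd.LadSimConfig(lads=lads, seed=SEED), layout)
    fio.write_track(OUT / "damid.bedgraph", track)
    sd.lads_to_frame(lads).to_csv(OUT / "lad_truth.tsv", sep="\t", index=False)
    n_lad_bp = sum(e - s for ivs in lads.values() for s, e in ivs)
    print(f"damid: {len(track)} bins, planted LADs cover "
          f"{100 * n_lad_bp / layout.total_bp:.0f}% of the genome")

    labels = {
        m.gene_id: sd.position_in_lads(lads, m.chrom, (m.region_start + m.region_end) // 2)
        for m in models
    }
    counts, de_truth = sd.simulate_de_counts(sd.DESimConfig(seed=SEED), labels)
    counts.reset_index().to_csv(OUT / "de_counts.tsv", sep="\t", index=False)
    de_truth.to_csv(OUT / "de_truth.tsv", sep="\t", index=False)
    print(f"rna-seq: {len(counts)} genes x {counts.shape[1]} samples, "
          f"{int(de_truth['is_lad'].sum())} LAD genes")

    trip, trip_truth = sd.simulate_trip(sd.TripSimConfig(seed=SEED), lads, layout)
    fio.write_barcode_table(OUT / "trip_counts.tsv", trip)
    trip_truth.to_csv(OUT / "trip_truth.tsv", sep="\t", index=False)
    print(f"trip: {len(trip)} barcodes, {int(trip_truth['is_lad'].sum())} in LADs")


if __name__ == "__main__":
    main()
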