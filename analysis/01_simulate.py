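"""Generate the synthetic study inputs every downstream analysis consumes.

Emulates the study conditions: a 15-sample diploid cohort genotyped at
5,000 exome-like SNPs, four continental frequency panels of 100 diploids,
a reference catalog covering ~92% of sites, four pseudo-caller SV call
sets, and HVS1-like sequences evolved along a known 6-taxon tree.  Ten
percent of SNPs carry a planted +0.4 frequency shift so the scan has a
known signal to find.  Outputs land in results/sim/.
"""

from pathlib import Path

from tribescan import formats_io as fio
from tribescan import synthetic_data as synth

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 2024

cfg = synth.SimConfig(planted_fraction=0.10, planted_shift=0.4, seed=SEED)

if __name__ == "__main__":
    (OUT / "truth").mkdir(parents=True, exist_ok=True)
    sim = synth.simulate_panel_and_cohort(cfg)
    fio.write_tsv_panel(sim.panel, OUT / "panel.tsv")
    fio.write_vcf(
        sim.variants(), sim.sample_names, OUT / "cohort.vcf",
        contigs=[str(c) for c in range(1, 23)],
    )
    sim.truth.to_csv(OUT / "truth" / "planted.tsv", sep="\t", index=False)
    synth.simulate_catalog(cfg, sim.sites).to_csv(
        OUT / "catalog.tsv", sep="\t", index=False
    )
    calls, sv_truth = synth.simulate_sv_callsets(cfg)
    calls.to_csv(OUT / "sv_calls.tsv", sep="\t", index=False)
    sv_truth.to_csv(OUT / "truth" / "sv_events.tsv", sep="\t", index=False)
    seqs, tree = synth.simulate_sequences(cfg)
    fio.write_fasta(seqs, OUT / "sequences.fasta")
    fio.write_newick(tree, OUT / "truth" / "true_tree.nwk")
    print(f"cohort: {cfg.n_snps} SNPs x {cfg.n_samples_study} samples "
          f"({int(sim.truth['planted'].sum())} planted)")
    print(f"panel: {len(sim.panel)} rows, {len(cfg.populations)} populations")
    print(f"SV: {len(calls)} calls over {len(sv_truth)} true events")
    print(f"sequences: {len(seqs)} tips x {cfg.seq_len} bp")
    print(f"wrote inputs to {OUT}")
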