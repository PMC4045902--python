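"""Build the three phylogenetic summaries on synthetic genomes/sequences.

(1) Genome-wide: per-autosome shared-variant distance matrices over 10
synthetic genomes from two 'ethnicity' clusters, one NJ tree per autosome,
then the majority-rule extended consensus annotated by the number of
autosomes supporting each branch.  (2) Disease-gene-restricted: the same
genomes restricted to flagged (OMIM-like) variant locations, genome-wide
distance, NJ with 50 bootstrap resamples over flagged locations.  (3)
Sequence-based: 100-replicate K2P/NJ bootstrap consensus of the simulated
HVS1-like alignment.  Writes Newick files under results/trees/.
"""

from pathlib import Path

import numpy as np

from tribescan import formats_io as fio
from tribescan import phylo
from tribescan.formats_io import SiteKey

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = ROOT / "sim", ROOT / "trees"
SEED = 2024
N_GENOMES_PER_GROUP = 5
N_CONTIGS = 22


def synth_genomes(rng):
    """Two clusters of genomes sharing cluster-private variant pools."""
    universe = [
        SiteKey(str(1 + i % N_CONTIGS), 500 * (i + 1)) for i in range(8000)
    ]
    shared = set(s for s in universe if rng.random() < 0.5)
    pools = {
        "grpA": {s for s in universe if rng.random() < 0.25},
        "grpB": {s for s in universe if rng.random() < 0.25},
    }
    genomes = {}
    for grp, pool in pools.items():
        for k in range(N_GENOMES_PER_GROUP):
            keep = {s for s in shared if rng.random() < 0.8}
            keep |= {s for s in pool if rng.random() < 0.8}
            genomes[f"{grp}_{k}"] = keep
    return genomes


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    genomes = synth_genomes(rng)

    # (1) per-autosome NJ + consensus, support = number of autosomes
    mats = phylo.per_chromosome_distance_matrices(
        genomes, contigs=[str(c) for c in range(1, N_CONTIGS + 1)]
    )
    trees = [
        phylo.collapse_zero_length(phylo.neighbor_joining(dm)) for _, dm in mats
    ]
    consensus = phylo.majority_consensus(trees)
    fio.write_newick(consensus, OUT / "genome_consensus.nwk")
    splits = phylo.bipartitions(consensus)
    group_split = frozenset(l for l in genomes if l.startswith("grpB"))
    seen = {frozenset(s): n.support for s, n in splits.items()}
    print(f"genome-wide consensus over {len(trees)} autosome trees: "
          f"{len(splits)} supported branches")
    print(f"  group split recovered with support "
          f"{seen.get(group_split, 0)}/{len(trees)} autosomes")

    # (2) disease-gene-restricted distances, bootstrap over flagged locations
    flagged = {s for s in set().union(*genomes.values()) if rng.random() < 0.10}
    flagged_list = sorted(flagged)
    reps = []
    for b in range(50):
        res = rng.integers(0, len(flagged_list), size=len(flagged_list))
        bag = {flagged_list[i] for i in res}
        dm = phylo.flagged_distance_matrix(genomes, bag)
        reps.append(phylo.collapse_zero_length(phylo.neighbor_joining(dm)))
    omim_cons = phylo.majority_consensus(reps)
    fio.write_newick(omim_cons, OUT / "omim_consensus.nwk")
    omim_seen = {
        frozenset(s): n.support for s, n in phylo.bipartitions(omim_cons).items()
    }
    print(f"flagged-variant consensus over 50 bootstraps: group split support "
          f"{omim_seen.get(group_split, 0)}/50")

    # (3) sequence bootstrap (HVS1-like alignment from 01_simulate)
    seqs = fio.read_fasta(SIM / "sequences.fasta", require_aligned=True)
    seq_cons = phylo.bootstrap_tree(seqs, n_reps=100, seed=SEED)
    fio.write_newick(seq_cons, OUT / "hvs1_consensus.nwk")
    true_tree = fio.read_newick(SIM / "truth" / "true_tree.nwk")
    got = {
        frozenset(s): n.support for s, n in phylo.bipartitions(seq_cons).items()
    }
    supports = [got.get(frozenset(s), 0) for s in phylo.bipartitions(true_tree)]
    print(f"sequence bootstrap consensus: true-branch supports {supports} / 100")
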