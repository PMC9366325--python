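"""Generate the synthetic senescence methylome dataset.

Writes the 400-kb two-chromosome genome with genes, TEs and planted
W-/bZIP-boxes, plus 12 Bismark-style CX reports (4 stages x 3 replicates)
with early CG loss, late CHH gain and beta-binomial replicate noise, and
the ground-truth tables, under results/data/.
"""

import importlib

from senemeth.simulate import write_fixture_set

cfg_mod = importlib.import_module("00_config")


def main():
    genome, features, truth = write_fixture_set(cfg_mod.CONFIG, cfg_mod.DATA_DIR)
    n_genes = (features["kind"] == "gene").sum()
    n_tes = (features["kind"] == "TE").sum()
    print(f"genome: {sum(map(len, genome.values()))} bp over {len(genome)} chromosomes")
    print(f"features: {n_genes} genes, {n_tes} TEs")
    print(f"cytosine sites simulated: {len(truth.sites)}")
    print(f"planted differential regions: {len(truth.planted_regions)}; "
          f"isolated sites: {len(truth.planted_sites)}")
    print(f"planted motif instances: {len(truth.motifs)}")
    print(f"dataset written to {cfg_mod.DATA_DIR}")


if __name__ == "__main__":
    main()
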