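"""Shared settings for the numbered analysis drivers.

One desk-scale synthetic experiment (400 kb genome over 2 chromosomes,
4 stages x 3 replicates) feeds every step; 01_simulate.py materialises it
under results/data and the later drivers load it from there.
"""

from pathlib import Path

from senemeth.simulate import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results"

SEED = 20260927

CONFIG = SyntheticConfig(
    genome_length=400_000,
    n_chromosomes=2,
    n_genes=80,
    n_tes=40,
    rng_seed=SEED,
)

STAGES = list(CONFIG.stages)


def load_dataset():
    """Genome, features, truth tables and the 12 coverage-filtered samples."""
    import pandas as pd
    from senemeth.io import read_genome, read_features, read_cx_report, filter_coverage

    if not DATA_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    genome = read_genome(DATA_DIR / "genome.fa")
    features = read_features(DATA_DIR / "features.gff3")
    features["kind"] = features["kind"].replace({"transposable_element": "TE"})
    samples = []
    for stage in STAGES:
        for rep in range(1, CONFIG.n_replicates + 1):
            s = read_cx_report(DATA_DIR / f"{stage}_rep{rep}.CX_report.txt",
                               stage=stage, replicate=str(rep))
            samples.append(filter_coverage(s))
    truth_sites = pd.read_csv(DATA_DIR / "truth_sites.tsv", sep="\t")
    return genome, features, samples, truth_sites
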