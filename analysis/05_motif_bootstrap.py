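"""Binding-site methylation: W-box and bZIP boxes vs matched background.

Scans the genome for TTGACT/TTGACC (WRKY W-box) and the palindromic bZIP
A/C/G-boxes, classifies motif cytosines by context, and compares their
mean methylation with same-context same-compartment background through the
without-replacement bootstrap (B = 2000 here). Also counts DML/motif
coincidences.
"""

import importlib

import numpy as np
import pandas as pd

from senemeth.architecture import derive_promoters, assign_compartment
from senemeth.motifs import (
    DEFAULT_MOTIFS, scan_motifs, motif_cytosines, bootstrap_motif_test,
    count_dml_in_motifs,
)

cfg_mod = importlib.import_module("00_config")

COMP3 = {"TE_in_promoter": "TE", "TE_outside_promoter": "TE",
         "ORF": "ORF", "promoter_no_TE": "promoter"}


def main():
    genome, features, samples, _truth = cfg_mod.load_dataset()
    genes = features[features["kind"] == "gene"].reset_index(drop=True)
    tes = features[features["kind"] == "TE"].reset_index(drop=True)
    promoters = derive_promoters(genes, 2500, {c: len(genome[c]) for c in genome})

    occ = scan_motifs(genome, DEFAULT_MOTIFS)
    print("motif occurrences (both strands, palindromes deduplicated):")
    print(occ.groupby("motif").size().to_string())

    cyt = motif_cytosines(occ, genome)
    cyt_comp = pd.Series(assign_compartment(
        cyt["chrom"].to_numpy(), cyt["pos"].to_numpy() - 1, genes, tes, promoters
    )).map(COMP3)
    fam = np.where(cyt["motif"] == "W-box", "W-box", "bZIP")

    blt = [s for s in samples if s.stage == "Blt"]
    frames = []
    for r in blt:
        cov = r.records["n_meth"] + r.records["n_unmeth"]
        sub = r.records.loc[cov > 0, ["chrom", "pos", "strand", "context"]].copy()
        sub["beta"] = (r.records.loc[cov > 0, "n_meth"] / cov[cov > 0]).to_numpy()
        frames.append(sub)
    site_beta = (pd.concat(frames).groupby(["chrom", "pos", "strand", "context"])["beta"]
                 .mean().reset_index())
    bg_comp = pd.Series(assign_compartment(
        site_beta["chrom"].to_numpy(), site_beta["pos"].to_numpy() - 1,
        genes, tes, promoters,
    )).map(COMP3)
    sb = site_beta.set_index(["chrom", "pos", "strand"])["beta"]

    rng = np.random.default_rng(cfg_mod.SEED + 5)
    rows = []
    print("\nbootstrap at Blt (motif mean vs matched background):")
    for comp in ("promoter", "ORF", "TE"):
        for family, ctx in (("W-box", "CHH"), ("W-box", "CHG"), ("bZIP", "CG")):
            sel = (fam == family) & (cyt["context"] == ctx).to_numpy() & (cyt_comp == comp).to_numpy()
            keys = pd.MultiIndex.from_frame(cyt.loc[sel, ["chrom", "pos", "strand"]])
            vals = sb.reindex(keys.unique()).dropna().to_numpy()
            bg = sb.to_numpy()[(bg_comp == comp).to_numpy()
                               & (site_beta["context"] == ctx).to_numpy()]
            if len(vals) < 3 or len(bg) < len(vals):
                continue
            r = bootstrap_motif_test(vals, bg, B=2000, seed=rng)
            rows.append((comp, ctx, family, r.observed_mean, r.null_mean, r.p_estimate, r.direction))
            print(f"  {family:<6} {ctx:<4} in {comp:<9}: observed {r.observed_mean:.4f} "
                  f"vs null {r.null_mean:.4f}  p={r.p_estimate:.4g} ({r.direction})")
    pd.DataFrame(rows, columns=["compartment", "context", "motif_family",
                                "observed_mean", "null_mean", "p", "direction"]) \
        .to_csv(cfg_mod.OUT_DIR / "motif_bootstrap_blt.tsv", sep="\t", index=False)

    dml_files = sorted(cfg_mod.OUT_DIR.glob("dml_*_vs_*.tsv"))
    if dml_files:
        dmls = pd.concat([pd.read_csv(p, sep="\t") for p in dml_files])
        dmls = dmls[dmls["is_dml"]].drop_duplicates(["chrom", "pos", "strand"])
        hits = count_dml_in_motifs(dmls, occ)
        hits.to_csv(cfg_mod.OUT_DIR / "dml_in_motifs.tsv", sep="\t", index=False)
        print("\nDMLs inside motif instances:")
        print(hits.to_string(index=False))


if __name__ == "__main__":
    main()
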