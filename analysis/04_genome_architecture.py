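"""Where does methylation change? Compartment and metagene views.

Computes stage x compartment x context mean methylation (promoters, ORFs,
TEs, whole genome), the exclusive compartment composition of DML sites,
and strand-aware metagene profiles of genes longer than 400 bp with
1000-bp flanks.
"""

import importlib

import pandas as pd

from senemeth.architecture import (
    derive_promoters, assign_compartment, methylation_by_compartment,
    metagene_profile,
)

cfg_mod = importlib.import_module("00_config")


def main():
    genome, features, samples, _truth = cfg_mod.load_dataset()
    genes = features[features["kind"] == "gene"].reset_index(drop=True)
    tes = features[features["kind"] == "TE"].reset_index(drop=True)
    promoters = derive_promoters(genes, 2500, {c: len(genome[c]) for c in genome})

    comp = methylation_by_compartment(samples, genes, tes, promoters)
    comp.to_csv(cfg_mod.OUT_DIR / "methylation_by_compartment.tsv", sep="\t", index=False)
    cg = comp[(comp["compartment"] == "total") & (comp["context"] == "CG")]
    print("genome-wide CG methylation by stage (expect a dip at SD):")
    for r in cg.itertuples():
        print(f"  {r.stage:<5} {r.mean_meth:.4f}")

    prof = metagene_profile(samples, genes, flank=1000, min_gene_len=400)
    prof.to_csv(cfg_mod.OUT_DIR / "metagene_profile.tsv", sep="\t", index=False)
    body = prof[(prof["region"] == "body")].groupby("context")["mean_meth"].mean()
    print("\nmean gene-body methylation per context:")
    print(body.to_string(float_format="%.4f"))

    # compartment composition of DML sites from the 03 step, if present
    dml_files = sorted(cfg_mod.OUT_DIR.glob("dml_*_vs_*.tsv"))
    if dml_files:
        dmls = pd.concat([pd.read_csv(p, sep="\t") for p in dml_files])
        dmls = dmls[dmls["is_dml"]].drop_duplicates(["chrom", "pos", "strand"])
        labels = assign_compartment(dmls["chrom"].to_numpy(),
                                    dmls["pos"].to_numpy() - 1,
                                    genes, tes, promoters)
        frac = pd.Series(labels).value_counts(normalize=True)
        frac.rename("fraction").to_csv(cfg_mod.OUT_DIR / "dml_compartment_fractions.tsv", sep="\t")
        print("\nDML compartment composition:")
        print(frac.to_string(float_format="%.3f"))


if __name__ == "__main__":
    main()
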