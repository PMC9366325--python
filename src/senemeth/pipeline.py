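"""End-to-end orchestration: simulate/load -> filter -> test all pairwise
stage comparisons -> annotate compartments -> motif/bootstrap -> report.

Driven by a declarative YAML config (:class:`PipelineConfig`). Every knob
defaults to the study's analysis settings: coverage 3-40x kept, DML delta
0.25 at p.threshold 0.05, DMR merge distance 100 bp, 2500-bp promoters,
50-bp concordance bins. Seeds are mandatory members of the config so the
simulator and the bootstrap are exactly reproducible; rerunning an
unchanged config reproduces the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    MethylomeSample,
    read_genome,
    read_features,
    read_cx_report,
    filter_coverage,
    write_bed,
)
from .simulate import SyntheticConfig, write_fixture_set
from .diffmeth import (
    build_group_counts,
    estimate_dispersion,
    dml_test,
    call_dml,
    call_dmr,
    summarize_dml,
)
from .architecture import (
    derive_promoters,
    assign_compartment,
    methylation_by_compartment,
    metagene_profile,
    sample_concordance,
)
from .motifs import (
    DEFAULT_MOTIFS,
    MotifDef,
    scan_motifs,
    motif_cytosines,
    bootstrap_motif_test,
    count_dml_in_motifs,
    count_motifs_in_dmrs,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "senemeth_run"
    # either a synthetic block or explicit input paths
    synthetic: dict | None = None
    genome_fasta: str | None = None
    features_gff: str | None = None
    samples: list | None = None  # [{stage, replicate, path}, ...]
    stages: list = field(default_factory=lambda: ["Blt", "Flwr", "SD", "SM"])
    min_cov: int = 3
    max_cov: int = 40
    delta: float = 0.25
    p_threshold: float = 0.05
    dmr_delta: float = 0.0
    dmr_min_len: int = 50
    dmr_min_cg: int = 3
    dmr_pct_sig: float = 0.5
    dmr_merge_dist: int = 100
    promoter_length: int = 2500
    bin_size: int = 50
    motif_scan_strands: str = "both"
    bootstrap_B: int = 2000
    bootstrap_max_background: int = 20000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_inputs(config: PipelineConfig, out: Path):
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("rng_seed", config.seed)
        for key in ("gene_length", "te_length", "dmr_sites", "stages"):
            if key in syn and isinstance(syn[key], list):
                syn[key] = tuple(syn[key])
        sconf = SyntheticConfig(**syn)
        data = out / "data"
        genome, features, truth = write_fixture_set(sconf, data)
        samples = []
        for stage in sconf.stages:
            for rep in range(1, sconf.n_replicates + 1):
                samples.append(
                    read_cx_report(
                        data / f"{stage}_rep{rep}.CX_report.txt",
                        stage=stage,
                        replicate=str(rep),
                    )
                )
        stages = list(sconf.stages)
        return genome, features, samples, stages, truth
    if not (config.genome_fasta and config.features_gff and config.samples):
        raise ValueError("config needs either a synthetic block or explicit input paths")
    genome = read_genome(config.genome_fasta)
    feats = read_features(config.features_gff)
    feats["kind"] = feats["kind"].replace({"transposable_element": "TE"})
    samples = [
        read_cx_report(s["path"], stage=s["stage"], replicate=str(s["replicate"]))
        for s in config.samples
    ]
    return genome, feats, samples, list(config.stages), None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the result bundle.

    All tables are also written under ``config.outdir``. Stages are
    compared in all pairwise combinations (6 for the 4-stage design).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    try:
        bundle = _run(config, out)
    except Exception:
        failed_marker.write_text("pipeline failed; partial outputs retained\n")
        raise
    failed_marker.unlink(missing_ok=True)
    return bundle


def _run(config: PipelineConfig, out: Path) -> dict:
    genome, features, samples, stages, truth = _load_inputs(config, out)
    if len(stages) < 2:
        raise ValueError("need at least two stages")

    filtered = []
    attrition = []
    for s in samples:
        f = filter_coverage(s, config.min_cov, config.max_cov)
        attrition.append((s.label(), len(s), len(f)))
        logger.info("filter %s: %d -> %d records", s.label(), len(s), len(f))
        filtered.append(f)
    pd.DataFrame(attrition, columns=["sample", "n_in", "n_out"]).to_csv(
        out / "filter_attrition.tsv", sep="\t", index=False
    )

    dist, scores, explained = sample_concordance(filtered, bin_size=config.bin_size)
    dist.to_csv(out / "concordance_manhattan.tsv", sep="\t")
    scores.to_csv(out / "concordance_pca_scores.tsv", sep="\t")

    genes = features[features["kind"] == "gene"].reset_index(drop=True)
    tes = features[features["kind"] == "TE"].reset_index(drop=True)
    chrom_lengths = {c: len(genome[c]) for c in genome}
    promoters = derive_promoters(genes, config.promoter_length, chrom_lengths)
    write_bed(promoters, out / "promoters.bed")

    by_stage: dict[str, list[MethylomeSample]] = {}
    for s in filtered:
        by_stage.setdefault(s.stage, []).append(s)

    dml_by_comp: dict[str, pd.DataFrame] = {}
    dmr_by_comp: dict[str, pd.DataFrame] = {}
    for s1, s2 in itertools.combinations(stages, 2):
        name = f"{s1}_vs_{s2}"
        counts = build_group_counts(by_stage[s1], by_stage[s2])
        phi = estimate_dispersion(counts)
        res = dml_test(counts, phi)
        flagged = call_dml(res, delta=config.delta, p_threshold=config.p_threshold)
        dml_by_comp[name] = flagged
        flagged.to_csv(out / f"dml_{name}.tsv", sep="\t", index=False)
        dmr = call_dmr(
            flagged,
            delta=config.dmr_delta,
            p_threshold=config.p_threshold,
            min_len=config.dmr_min_len,
            min_cg=config.dmr_min_cg,
            pct_sig=config.dmr_pct_sig,
            merge_dist=config.dmr_merge_dist,
        )
        dmr_by_comp[name] = dmr
        dmr.to_csv(out / f"dmr_{name}.tsv", sep="\t", index=False)
        logger.info("%s: %d DMLs, %d DMRs", name, int(flagged["is_dml"].sum()), len(dmr))

    summary = summarize_dml(dml_by_comp)
    summary["composition"].to_csv(out / "dml_composition.tsv", sep="\t", index=False)

    compmeth = methylation_by_compartment(filtered, genes, tes, promoters)
    compmeth.to_csv(out / "methylation_by_compartment.tsv", sep="\t", index=False)

    metagene = metagene_profile(filtered, genes)
    metagene.to_csv(out / "metagene_profile.tsv", sep="\t", index=False)

    # exclusive compartment composition of the DML union
    union = pd.concat(
        [df[df["is_dml"]][["chrom", "pos", "strand"]] for df in dml_by_comp.values()]
    ).drop_duplicates()
    if not union.empty:
        labels = assign_compartment(
            union["chrom"].to_numpy(), union["pos"].to_numpy() - 1, genes, tes, promoters
        )
        frac = pd.Series(labels).value_counts(normalize=True).rename("fraction")
        frac.to_csv(out / "dml_compartment_fractions.tsv", sep="\t")

    # motif analysis
    motifs = tuple(
        MotifDef(m.name, m.patterns, scan_strands=config.motif_scan_strands)
        for m in DEFAULT_MOTIFS
    )
    occurrences = scan_motifs(genome, motifs)
    write_bed(
        occurrences.assign(id=occurrences["motif"], strand=occurrences["strand"]),
        out / "motif_occurrences.bed",
    )
    cyt = motif_cytosines(occurrences, genome)
    cyt_comp = assign_compartment(
        cyt["chrom"].to_numpy(), cyt["pos"].to_numpy() - 1, genes, tes, promoters
    )
    comp3 = {
        "TE_in_promoter": "TE", "TE_outside_promoter": "TE",
        "ORF": "ORF", "promoter_no_TE": "promoter",
    }
    boot_rows = []
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(9,)))
    cells = [("W-box", "CHH"), ("W-box", "CHG"), ("bZIP", "CG")]
    fam = np.where(cyt["motif"] == "W-box", "W-box", "bZIP")
    for stage, reps in by_stage.items():
        site_beta = _replicate_mean_beta(reps)
        sb = site_beta.set_index(["chrom", "pos", "strand"])["beta"]
        comp_of_bg = assign_compartment(
            site_beta["chrom"].to_numpy(), site_beta["pos"].to_numpy() - 1,
            genes, tes, promoters,
        )
        bg3 = pd.Series(comp_of_bg).map(comp3)
        for comp in ("promoter", "ORF", "TE"):
            for family, ctx in cells:
                sel = (
                    (fam == family)
                    & (cyt["context"] == ctx).to_numpy()
                    & (pd.Series(cyt_comp).map(comp3) == comp).to_numpy()
                )
                keys = pd.MultiIndex.from_frame(cyt.loc[sel, ["chrom", "pos", "strand"]])
                vals = sb.reindex(keys.unique()).dropna().to_numpy()
                bgsel = (
                    (bg3 == comp).to_numpy()
                    & (site_beta["context"] == ctx).to_numpy()
                )
                bg = sb.to_numpy()[bgsel]
                if len(vals) == 0 or len(bg) < max(len(vals), 2):
                    continue
                if len(bg) > config.bootstrap_max_background:
                    bg = rng.choice(bg, config.bootstrap_max_background, replace=False)
                if len(bg) < len(vals):
                    continue
                r = bootstrap_motif_test(vals, bg, B=config.bootstrap_B, seed=rng)
                boot_rows.append(
                    (stage, comp, ctx, family, r.observed_mean, r.null_mean,
                     r.null_sd, r.p_estimate, r.direction, r.n_motif_cytosines,
                     r.n_background)
                )
    bootstrap = pd.DataFrame(
        boot_rows,
        columns=["stage", "compartment", "context", "motif_family", "observed_mean",
                 "null_mean", "null_sd", "p_estimate", "direction",
                 "n_motif_cytosines", "n_background"],
    )
    bootstrap.to_csv(out / "motif_bootstrap.tsv", sep="\t", index=False)

    union_dml = pd.concat(
        [df[df["is_dml"]] for df in dml_by_comp.values()]
    ).drop_duplicates(subset=["chrom", "pos", "strand"])
    dml_in_motifs = count_dml_in_motifs(union_dml, occurrences)
    dml_in_motifs.to_csv(out / "dml_in_motifs.tsv", sep="\t", index=False)

    nonempty = [d.assign(comparison=nm) for nm, d in dmr_by_comp.items() if not d.empty]
    all_dmrs = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=["chrom", "start", "end", "context", "n_sites",
                                   "n_sig_sites", "mean_diff", "area_stat", "direction",
                                   "comparison"])
    )
    if not all_dmrs.empty:
        all_dmrs["id"] = [f"dmr{i:05d}" for i in range(len(all_dmrs))]
    motifs_in_dmrs = count_motifs_in_dmrs(all_dmrs, occurrences, promoters, tes)
    motifs_in_dmrs.to_csv(out / "motifs_in_dmrs.tsv", sep="\t", index=False)

    manifest = {
        "senemeth_version": __version__,
        "seed": int(config.seed),
        "stages": stages,
        "comparisons": sorted(dml_by_comp),
        "parameters": dataclasses.asdict(config),
    }
    data_manifest = out / "data" / "manifest.yaml"
    if data_manifest.exists():
        with open(data_manifest) as fh:
            manifest["synthetic_config_hash"] = yaml.safe_load(fh)["config_hash"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)

    bundle = {
        "outdir": str(out),
        "dml": dml_by_comp,
        "dmr": dmr_by_comp,
        "summary": summary,
        "concordance": (dist, scores, explained),
        "methylation_by_compartment": compmeth,
        "metagene": metagene,
        "bootstrap": bootstrap,
        "dml_in_motifs": dml_in_motifs,
        "motifs_in_dmrs": motifs_in_dmrs,
        "truth": truth,
        "manifest": manifest,
    }
    (out / "report.md").write_text(make_report(bundle))
    return bundle


def _replicate_mean_beta(reps: list[MethylomeSample]) -> pd.DataFrame:
    frames = []
    for r in reps:
        df = r.records
        cov = df["n_meth"] + df["n_unmeth"]
        sub = df.loc[cov > 0, ["chrom", "pos", "strand", "context"]].copy()
        sub["beta"] = (df.loc[cov > 0, "n_meth"] / cov[cov > 0]).to_numpy()
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    return (
        pooled.groupby(["chrom", "pos", "strand", "context"], sort=True)["beta"]
        .mean()
        .reset_index()
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_report(bundle: dict) -> str:
    """Human-readable run summary; notes absent tables instead of failing."""
    lines = ["# senemeth run report", ""]
    dml = bundle.get("dml")
    if dml:
        lines.append("## Differential methylation")
        lines.append("")
        lines.append("| comparison | DMLs | hypo | hyper | DMRs |")
        lines.append("|---|---|---|---|---|")
        dmr = bundle.get("dmr", {})
        for name, df in dml.items():
            d = df[df["is_dml"]]
            lines.append(
                f"| {name} | {len(d)} | {(d['direction'] == 'hypo').sum()} | "
                f"{(d['direction'] == 'hyper').sum()} | {len(dmr.get(name, []))} |"
            )
        summary = bundle.get("summary")
        if summary:
            lines.append("")
            lines.append(
                f"Distinct DML sites: {summary['n_distinct_dmls']}; "
                f"fraction unique to one comparison: {summary['unique_fraction']:.3f}"
            )
    else:
        lines.append("Differential methylation tables: absent")
    lines.append("")
    comp = bundle.get("methylation_by_compartment")
    if comp is not None:
        lines.append("## Mean methylation by stage / compartment / context")
        lines.append("")
        lines.append(comp.to_csv(sep="\t", index=False, float_format="%.4f").rstrip())
    else:
        lines.append("Compartment methylation table: absent")
    lines.append("")
    boot = bundle.get("bootstrap")
    if boot is not None and len(boot):
        lines.append("## Motif-site methylation vs matched background (bootstrap)")
        lines.append("")
        lines.append(boot.to_csv(sep="\t", index=False, float_format="%.5f").rstrip())
    else:
        lines.append("Bootstrap table: absent")
    lines.append("")
    return "\n".join(lines)
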