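"""Synthetic methylome generator with planted senescence dynamics.

Emulates the structure of a 4-stage (Blt, Flwr, SD, SM) x 3-replicate
whole-genome bisulfite experiment on an AT-rich two-chromosome genome
carrying genes, transposable elements (TEs), derived promoter windows and
planted transcription-factor binding motifs.

The generative model, per cytosine site:

* a *true* methylation level ``beta = clip(baseline[compartment, context]
  + stage_shift[stage, compartment, context] + planted effects, 0, 1)``;
* replicate-level success probability ``p ~ Beta`` with mean ``beta`` and
  dispersion ``phi`` (``Beta(beta(1-phi)/phi, (1-beta)(1-phi)/phi)``), the
  beta-binomial overdispersion of biological replicates;
* coverage ``~ NegativeBinomial(mean, size)`` truncated at a ceiling, so
  some sites fall below/above the coverage filter by construction;
* ``n_meth ~ Binomial(coverage, p)``.

Planted differential elements are contiguous runs of 5-50 same-context
cytosines (region-shaped, what a DMR caller should find) plus isolated
single sites (DML-shaped), with stage-dependent additive shifts that follow
the senescence narrative: CG loss from bolting to seed development
(strongest in TEs), late CHH/CHG gain in TEs and promoters at seed
maturation. All randomness derives from one seed; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    CX_COLUMNS,
    MethylomeSample,
    derive_contexts_vectorized,
    write_cx_report,
    write_bed,
)

__all__ = [
    "SyntheticConfig",
    "TruthTables",
    "generate_genome",
    "build_truth",
    "simulate_methylome",
    "simulate_two_group_counts",
    "write_fixture_set",
]

STAGES = ("Blt", "Flwr", "SD", "SM")

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


def _default_baseline() -> dict:
    # mean true beta per (compartment, context); TE-heavy CG methylation,
    # sparse non-CG outside TEs: the Arabidopsis regime at coarse grain
    return {
        ("TE", "CG"): 0.85, ("TE", "CHG"): 0.40, ("TE", "CHH"): 0.10,
        ("gene", "CG"): 0.15, ("gene", "CHG"): 0.03, ("gene", "CHH"): 0.02,
        ("promoter", "CG"): 0.12, ("promoter", "CHG"): 0.05, ("promoter", "CHH"): 0.04,
        ("intergenic", "CG"): 0.10, ("intergenic", "CHG"): 0.04, ("intergenic", "CHH"): 0.03,
    }


def _default_stage_effects() -> dict:
    # additive beta shift vs Blt: early CG loss reaching a minimum at SD
    # (largest in TEs), partial CG recovery at SM, late CHH/CHG gain in TEs
    # and promoters beyond the Blt level
    eff = {}
    for comp in ("TE", "gene", "promoter", "intergenic"):
        te = comp == "TE"
        eff[("Flwr", comp, "CG")] = -0.06 if te else -0.04
        eff[("SD", comp, "CG")] = -0.15 if te else -0.10
        eff[("SM", comp, "CG")] = -0.06 if te else -0.04
        eff[("Flwr", comp, "CHG")] = -0.01
        eff[("SD", comp, "CHG")] = -0.05 if te else -0.03
        eff[("Flwr", comp, "CHH")] = -0.01
        eff[("SD", comp, "CHH")] = -0.04 if te else -0.03
    eff[("SM", "TE", "CHG")] = 0.04
    eff[("SM", "promoter", "CHG")] = 0.03
    eff[("SM", "gene", "CHG")] = 0.0
    eff[("SM", "intergenic", "CHG")] = 0.0
    eff[("SM", "TE", "CHH")] = 0.06
    eff[("SM", "promoter", "CHH")] = 0.05
    eff[("SM", "gene", "CHH")] = 0.01
    eff[("SM", "intergenic", "CHH")] = 0.01
    return eff


def _default_motif_plantings() -> dict:
    return {
        "W-box": {"promoter": 40, "gene": 40, "TE": 40, "intergenic": 40},
        "A-box": {"promoter": 15, "gene": 15, "TE": 15, "intergenic": 15},
        "C-box": {"promoter": 15, "gene": 15, "TE": 15, "intergenic": 15},
        "G-box": {"promoter": 15, "gene": 15, "TE": 15, "intergenic": 15},
    }


_MOTIF_SEQS = {
    "W-box": ("TTGACT", "TTGACC"),
    "A-box": ("TACGTA",),
    "C-box": ("GACGTC",),
    "G-box": ("CACGTG",),
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.36
    n_genes: int = 400
    n_tes: int = 200
    gene_length: tuple[int, int] = (600, 4000)
    te_length: tuple[int, int] = (400, 3000)
    te_in_promoter_fraction: float = 0.25
    promoter_length: int = 2500
    motif_plantings: dict = field(default_factory=_default_motif_plantings)
    motif_meth_shift: dict = field(
        default_factory=lambda: {"W-box": 0.10, "A-box": -0.05, "C-box": -0.05, "G-box": -0.05}
    )
    baseline: dict = field(default_factory=_default_baseline)
    stage_effects: dict = field(default_factory=_default_stage_effects)
    stages: tuple = STAGES
    n_replicates: int = 3
    dispersion: dict = field(default_factory=lambda: {"CG": 0.05, "CHG": 0.05, "CHH": 0.05})
    coverage_mean: float = 15.0
    coverage_size: float = 8.0
    coverage_max: int = 100
    # planted region-shaped differential elements (same-context cytosine runs)
    n_dmr_hypo_cg: int = 12        # TE CG loss, Blt -> SD, partial recovery at SM
    n_dmr_hyper_late: int = 12     # TE/promoter CHH (2/3) and CHG (1/3) gain at SM
    dmr_sites: tuple[int, int] = (5, 50)
    dmr_effect: float = 0.30
    # planted isolated differential single sites
    n_dml_hypo_cg: int = 30
    n_dml_hyper_late: int = 30
    dml_effect: float = 0.30
    rng_seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.rng_seed, spawn_key=key))


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic data.

    ``sites`` has one row per simulated cytosine with its compartment and
    one ``beta_<stage>`` column per stage; ``planted_regions`` and
    ``planted_sites`` record the differential elements with their defining
    stage pair, direction and effect size; ``motifs`` is the placement
    registry of planted binding sites.
    """

    sites: pd.DataFrame
    planted_regions: pd.DataFrame
    planted_sites: pd.DataFrame
    motifs: pd.DataFrame


# ---------------------------------------------------------------------------
# genome generation


def _place_nonoverlapping(rng, L, lengths, occupied, max_tries=200):
    """Place intervals of given lengths uniformly without overlap.

    ``occupied`` is a list of (start, end) tuples, updated in place.
    Returns list of (start, end). Raises when space runs out.
    """
    placed = []
    for ln in lengths:
        for _ in range(max_tries):
            s = int(rng.integers(0, max(L - ln, 1)))
            e = s + ln
            if all(e <= os or s >= oe for os, oe in occupied):
                occupied.append((s, e))
                placed.append((s, e))
                break
        else:
            raise ValueError(
                "could not place features without overlap; use fewer/shorter features"
            )
    return placed


def generate_genome(config: SyntheticConfig):
    """Generate the genome FASTA string set, feature table and motif registry.

    Returns ``(genome, features, motif_registry)`` where ``genome`` maps
    chromosome name to sequence, ``features`` is the 0-based half-open
    interval table (genes with strand, TEs), and ``motif_registry`` records
    each planted motif instance (chrom, start, end, strand, motif,
    compartment). A fraction of TEs is deliberately placed inside the
    promoter window upstream of genes so the TE-in-promoter compartment is
    populated. Deterministic given the config seed.
    """
    rng = config.rng(0)
    L = config.chrom_length()
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    chroms = config.chrom_names()
    seqs: dict[str, np.ndarray] = {
        c: _BASES[rng.choice(4, size=L, p=probs)].copy() for c in chroms
    }

    rows = []
    occupied = {c: [] for c in chroms}
    # genes
    n_per = np.diff(np.linspace(0, config.n_genes, len(chroms) + 1).astype(int))
    gid = 0
    for c, n in zip(chroms, n_per):
        lens = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n)
        for s, e in _place_nonoverlapping(rng, L, lens, occupied[c]):
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((c, s, e, strand, "gene", f"gene{gid:05d}"))
            gid += 1
    genes = [r for r in rows if r[4] == "gene"]
    # TEs: some inside promoter windows of genes, rest uniform
    n_in_prom = int(round(config.n_tes * config.te_in_promoter_fraction))
    tid = 0
    te_rows = []
    gene_pool = list(genes)
    rng.shuffle(gene_pool)
    for g in gene_pool:
        if tid >= n_in_prom:
            break
        c, gs, ge, gstrand = g[0], g[1], g[2], g[3]
        ln = int(rng.integers(config.te_length[0], min(config.te_length[1], config.promoter_length) + 1))
        if gstrand == "+":
            lo, hi = max(gs - config.promoter_length, 0), gs
        else:
            lo, hi = ge, min(ge + config.promoter_length, L)
        if hi - lo < ln:
            continue
        for _ in range(50):
            s = int(rng.integers(lo, hi - ln + 1))
            e = s + ln
            if all(e <= os or s >= oe for os, oe in occupied[c]):
                occupied[c].append((s, e))
                te_rows.append((c, s, e, "+" if rng.random() < 0.5 else "-", "TE", f"te{tid:05d}"))
                tid += 1
                break
    n_rest = config.n_tes - tid
    n_per = np.diff(np.linspace(0, n_rest, len(chroms) + 1).astype(int))
    for c, n in zip(chroms, n_per):
        lens = rng.integers(config.te_length[0], config.te_length[1] + 1, size=n)
        for s, e in _place_nonoverlapping(rng, L, lens, occupied[c]):
            te_rows.append((c, s, e, "+" if rng.random() < 0.5 else "-", "TE", f"te{tid:05d}"))
            tid += 1
    rows += te_rows
    features = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "kind", "id"])
    features = features.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # compartment intervals for targeted motif planting
    comp_windows = _compartment_windows(features, L, chroms, config.promoter_length)

    motif_rows = []
    planted: dict[str, list] = {c: [] for c in chroms}
    for motif, per_comp in config.motif_plantings.items():
        variants = _MOTIF_SEQS[motif]
        for comp, count in per_comp.items():
            wins = comp_windows.get(comp, [])
            if count > 0 and not wins:
                raise ValueError(f"no {comp} space to plant {motif}")
            w_arr = np.array([w[2] - w[1] for w in wins], dtype=float)
            placed = 0
            tries = 0
            while placed < count:
                tries += 1
                if tries > 200 * count:
                    raise ValueError(f"could not plant {count} {motif} in {comp}")
                wi = int(rng.choice(len(wins), p=w_arr / w_arr.sum()))
                c, lo, hi = wins[wi]
                seqv = variants[int(rng.integers(len(variants)))]
                ln = len(seqv)
                if hi - lo < ln:
                    continue
                s = int(rng.integers(lo, hi - ln + 1))
                e = s + ln
                if any(e > ms and s < me for ms, me in planted[c]):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                written = seqv if strand == "+" else _revcomp_str(seqv)
                seqs[c][s:e] = np.frombuffer(written.encode(), dtype="S1")
                planted[c].append((s, e))
                motif_rows.append((c, s, e, strand, motif, comp))
                placed += 1
    registry = pd.DataFrame(
        motif_rows, columns=["chrom", "start", "end", "strand", "motif", "compartment"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    genome = {c: seqs[c].tobytes().decode("ascii") for c in chroms}
    return genome, features, registry


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _compartment_windows(features, L, chroms, promoter_length):
    """Disjoint-enough windows per compartment used for targeted planting."""
    wins: dict[str, list] = {"gene": [], "TE": [], "promoter": [], "intergenic": []}
    for _, f in features.iterrows():
        wins[f["kind"]].append((f["chrom"], int(f["start"]), int(f["end"])))
    for _, g in features[features["kind"] == "gene"].iterrows():
        if g["strand"] == "+":
            lo, hi = max(int(g["start"]) - promoter_length, 0), int(g["start"])
        else:
            lo, hi = int(g["end"]), min(int(g["end"]) + promoter_length, L)
        if hi > lo:
            wins["promoter"].append((g["chrom"], lo, hi))
    for c in chroms:
        sub = features[features["chrom"] == c]
        edges = sorted(zip(sub["start"].astype(int), sub["end"].astype(int)))
        prev = 0
        for s, e in edges:
            if s - prev > 200:
                wins["intergenic"].append((c, prev, s))
            prev = max(prev, e)
        if L - prev > 200:
            wins["intergenic"].append((c, prev, L))
    return wins


# ---------------------------------------------------------------------------
# truth construction


def _compartment_of_positions(features, promoters, chrom, pos0):
    """Vectorised compartment label per 0-based position, precedence
    TE > gene > promoter > intergenic."""
    lab = np.full(len(pos0), "intergenic", dtype="U10")
    for kind, name in (("promoter", "promoter"), ("gene", "gene"), ("TE", "TE")):
        src = promoters if kind == "promoter" else features[features["kind"] == kind]
        sub = src[src["chrom"] == chrom]
        if sub.empty:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(pos0), bool)
        inside[ok] = pos0[ok] < ends[idx[ok]]
        # intervals may overlap slightly; the later kinds overwrite earlier
        lab[inside] = name
    return lab


def build_truth(genome: Mapping[str, str], features: pd.DataFrame, config: SyntheticConfig) -> TruthTables:
    """Derive the site table and per-stage true methylation levels.

    Sites are all CG/CHG/CHH cytosines on both strands. True levels are the
    compartment x context baseline plus stage shifts plus planted elements
    (regions and isolated sites) plus motif shifts, clipped to [0, 1].
    """
    from .architecture import derive_promoters

    promoters = derive_promoters(features[features["kind"] == "gene"],
                                 length=config.promoter_length,
                                 chrom_lengths={c: len(genome[c]) for c in genome})
    frames = []
    for chrom in config.chrom_names():
        pos, strand, ctx = derive_contexts_vectorized(genome[chrom])
        keep = ctx != "NA"
        pos, strand, ctx = pos[keep], strand[keep], ctx[keep]
        comp = _compartment_of_positions(features, promoters, chrom, pos - 1)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": pos.astype(np.int64), "strand": strand,
             "context": ctx, "compartment": comp}
        ))
    sites = pd.concat(frames, ignore_index=True)

    base = np.empty(len(sites))
    for (comp, ctx), b in config.baseline.items():
        base[(sites["compartment"] == comp).to_numpy() & (sites["context"] == ctx).to_numpy()] = b

    betas = {}
    for stage in config.stages:
        shift = np.zeros(len(sites))
        if stage != config.stages[0]:
            for (st, comp, ctx), d in config.stage_effects.items():
                if st == stage:
                    shift[(sites["compartment"] == comp).to_numpy() & (sites["context"] == ctx).to_numpy()] += d
        betas[stage] = base + shift

    rng = config.rng(1)
    regions, planted_sites = _plant_elements(sites, betas, config, rng)

    # motif methylation shifts (applied after planting, before clipping)
    # handled by caller via registry? -> done in write_fixture_set/simulate by
    # passing registry; here we only know features. Motif shifts are applied
    # in apply_motif_shifts().
    for stage in config.stages:
        betas[stage] = np.clip(betas[stage], 0.0, 1.0)
        sites[f"beta_{stage}"] = betas[stage]
    return TruthTables(sites=sites, planted_regions=regions, planted_sites=planted_sites,
                       motifs=pd.DataFrame())


def apply_motif_shifts(truth: TruthTables, registry: pd.DataFrame, config: SyntheticConfig) -> TruthTables:
    """Shift true methylation of cytosines inside planted motif instances."""
    if registry.empty:
        return truth
    sites = truth.sites
    for chrom, sub in registry.groupby("chrom"):
        m = sites["chrom"] == chrom
        pos0 = sites.loc[m, "pos"].to_numpy() - 1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        shifts = np.array([config.motif_meth_shift.get(x, 0.0) for x in sub["motif"]])
        order = np.argsort(starts)
        starts, ends, shifts = starts[order], ends[order], shifts[order]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(pos0), bool)
        inside[ok] = pos0[ok] < ends[idx[ok]]
        delta = np.zeros(len(pos0))
        delta[inside] = shifts[idx[inside]]
        for stage in config.stages:
            col = f"beta_{stage}"
            vals = sites.loc[m, col].to_numpy()
            sites.loc[m, col] = np.clip(vals + delta, 0.0, 1.0)
    truth.motifs = registry
    return truth


def _plant_elements(sites, betas, config, rng):
    """Plant region runs and isolated sites; mutates ``betas`` in place."""
    stages = list(config.stages)
    region_rows, site_rows = [], []

    def runs_of(context, compartment, k):
        """Candidate runs of k consecutive same-context sites in a compartment."""
        m = (sites["context"] == context) & (sites["compartment"] == compartment)
        idx = np.flatnonzero(m.to_numpy())
        if len(idx) < k:
            return None
        start = int(rng.integers(0, len(idx) - k + 1))
        sel = idx[start : start + k]
        # keep the run on one chromosome and spatially contiguous
        ch = sites["chrom"].to_numpy()[sel]
        if (ch != ch[0]).any():
            return None
        p = sites["pos"].to_numpy()[sel]
        if k > 1 and np.diff(p).max() > 100:
            return None
        return sel

    taken = np.zeros(len(sites), bool)

    def plant(kind, context, compartment, deltas_by_stage, n, rid_prefix):
        planted = 0
        tries = 0
        while planted < n:
            tries += 1
            if tries > 500 * max(n, 1):
                raise ValueError(f"could not plant {n} {rid_prefix} elements")
            k = 1 if kind == "site" else int(rng.integers(config.dmr_sites[0], config.dmr_sites[1] + 1))
            sel = runs_of(context, compartment, k)
            if sel is None or taken[sel].any():
                continue
            taken[sel] = True
            for stage, d in deltas_by_stage.items():
                if stage in betas:
                    betas[stage][sel] += d
            ch = sites["chrom"].to_numpy()[sel][0]
            p = sites["pos"].to_numpy()[sel]
            stage_a, stage_b = _defining_pair(deltas_by_stage, stages)
            d_def = deltas_by_stage[stage_b] - deltas_by_stage.get(stage_a, 0.0)
            row = (f"{rid_prefix}{planted:04d}", ch, int(p.min() - 1), int(p.max()),
                   context, compartment, k, stage_a, stage_b, float(d_def),
                   "hyper" if d_def > 0 else "hypo")
            (site_rows if kind == "site" else region_rows).append(row)
            planted += 1

    hypo = {"Flwr": -0.15, "SD": -config.dmr_effect, "SM": -0.10}
    hypo = {s: d for s, d in hypo.items() if s in stages} or {stages[-1]: -config.dmr_effect}
    late_stage = stages[-1]
    late = {late_stage: config.dmr_effect}
    # region-shaped elements
    plant("region", "CG", "TE", hypo, config.n_dmr_hypo_cg, "dmr_hypo_cg")
    n_chh = (2 * config.n_dmr_hyper_late) // 3
    n_chg = config.n_dmr_hyper_late - n_chh
    plant("region", "CHH", "TE", late, (n_chh + 1) // 2, "dmr_hyper_chh_te")
    plant("region", "CHH", "promoter", late, n_chh // 2, "dmr_hyper_chh_prom")
    plant("region", "CHG", "TE", late, n_chg, "dmr_hyper_chg_te")
    # isolated sites
    hypo1 = {"Flwr": -0.15, "SD": -config.dml_effect, "SM": -0.10}
    hypo1 = {s: d for s, d in hypo1.items() if s in stages} or {stages[-1]: -config.dml_effect}
    late1 = {late_stage: config.dml_effect}
    plant("site", "CG", "TE", hypo1, config.n_dml_hypo_cg, "dml_hypo_cg")
    n_chh = (2 * config.n_dml_hyper_late) // 3
    n_chg = config.n_dml_hyper_late - n_chh
    plant("site", "CHH", "TE", late1, (n_chh + 1) // 2, "dml_hyper_chh_te")
    plant("site", "CHH", "promoter", late1, n_chh // 2, "dml_hyper_chh_prom")
    plant("site", "CHG", "TE", late1, n_chg, "dml_hyper_chg_te")

    cols = ["id", "chrom", "start", "end", "context", "compartment", "n_sites",
            "stage_a", "stage_b", "delta", "direction"]
    return (pd.DataFrame(region_rows, columns=cols),
            pd.DataFrame(site_rows, columns=cols))


def _defining_pair(deltas, stages):
    """The stage pair across which the planted |delta| is largest."""
    vals = {s: deltas.get(s, 0.0) for s in stages}
    lo = min(stages, key=lambda s: abs(vals[s]))
    hi = max(stages, key=lambda s: abs(vals[s]))
    return (lo, hi) if stages.index(lo) < stages.index(hi) else (hi, lo)


# ---------------------------------------------------------------------------
# sampling


def _trinucleotides(seq: str, pos: np.ndarray, strand: np.ndarray) -> np.ndarray:
    padded = seq + "NN"
    arr = np.frombuffer(padded.encode("ascii"), dtype="S1")
    i = pos - 1
    out = np.empty(len(pos), dtype="U3")
    plus = strand == "+"
    b0 = arr[i].astype("U1")
    b1 = arr[np.minimum(i + 1, len(arr) - 1)].astype("U1")
    b2 = arr[np.minimum(i + 2, len(arr) - 1)].astype("U1")
    fw = np.char.add(np.char.add(b0, b1), b2)
    out[plus] = fw[plus]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    cb = np.array([comp[x] for x in "ACGTN"])
    lut = np.full(256, "N", dtype="U1")
    for x, y in comp.items():
        lut[ord(x)] = y
    m0 = lut[arr[i].view(np.uint8)]
    m1 = lut[arr[np.maximum(i - 1, 0)].view(np.uint8)]
    m2 = lut[arr[np.maximum(i - 2, 0)].view(np.uint8)]
    rv = np.char.add(np.char.add(m0, m1), m2)
    out[~plus] = rv[~plus]
    # edge padding: positions 1 and 2 on - strand have <2 downstream bases
    out[(~plus) & (i == 0)] = np.char.add(m0[(~plus) & (i == 0)], "NN")
    sel = (~plus) & (i == 1)
    out[sel] = np.char.add(np.char.add(m0[sel], m1[sel]), "N")
    return out


def simulate_methylome(
    genome: Mapping[str, str],
    features: pd.DataFrame,
    config: SyntheticConfig,
    stage: str,
    replicate: int,
    truth: TruthTables | None = None,
) -> tuple[MethylomeSample, TruthTables]:
    """Draw one replicate's per-cytosine counts for one stage.

    Noise is replicate-specific (beta-binomial with per-context dispersion,
    truncated negative-binomial coverage) while the underlying truth is
    shared across replicates. Returns the sample and the truth tables.
    """
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    for phi in config.dispersion.values():
        if not (0.0 < phi < 1.0):
            raise ValueError("dispersion must lie in (0, 1)")
    if truth is None:
        truth = build_truth(genome, features, config)
    sites = truth.sites
    beta = sites[f"beta_{stage}"].to_numpy()
    si = list(config.stages).index(stage)
    rng = config.rng(2, si, int(replicate))

    phi = np.empty(len(sites))
    for ctx, v in config.dispersion.items():
        phi[(sites["context"] == ctx).to_numpy()] = v
    p = np.where(beta <= 0.0, 0.0, np.where(beta >= 1.0, 1.0, np.nan))
    mid = np.isnan(p)
    a = beta[mid] * (1 - phi[mid]) / phi[mid]
    b = (1 - beta[mid]) * (1 - phi[mid]) / phi[mid]
    p[mid] = rng.beta(a, b)

    size = config.coverage_size
    cov = rng.negative_binomial(size, size / (size + config.coverage_mean), len(sites))
    cov = np.minimum(cov, config.coverage_max)
    n_meth = rng.binomial(cov, p)

    frames = []
    for chrom in config.chrom_names():
        m = (sites["chrom"] == chrom).to_numpy()
        pos = sites["pos"].to_numpy()[m]
        strand = sites["strand"].to_numpy()[m]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "n_meth": n_meth[m],
            "n_unmeth": cov[m] - n_meth[m],
            "context": sites["context"].to_numpy()[m],
            "trinucleotide": _trinucleotides(genome[chrom], pos, strand),
        }))
    df = pd.concat(frames, ignore_index=True)
    return MethylomeSample(stage=stage, replicate=str(replicate), records=df), truth


def simulate_two_group_counts(
    beta1: np.ndarray,
    beta2: np.ndarray,
    phi: float = 0.05,
    n_reps: int = 3,
    coverage_mean: float = 15.0,
    coverage_size: float = 8.0,
    seed: int = 0,
    spacing: int = 10,
    context: str = "CG",
    chrom: str = "chr1",
):
    """Beta-binomial two-group counts for given per-site true levels.

    A direct route to :class:`~senemeth.diffmeth.GroupCounts` without a
    genome: sites are laid out ``spacing`` bp apart on one chromosome,
    every replicate draws ``p ~ Beta(mean beta, dispersion phi)`` and
    ``n_meth ~ Binomial(NegBin coverage, p)``. Used for statistical
    calibration (null simulations, planted-region recovery).
    """
    from .diffmeth import GroupCounts

    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape:
        raise ValueError("beta1 and beta2 must have equal length")
    rng = np.random.default_rng(seed)
    n_sites = len(beta1)

    def draw(beta):
        x = np.empty((n_sites, n_reps))
        n = np.empty((n_sites, n_reps))
        for j in range(n_reps):
            p = np.where(beta <= 0, 0.0, np.where(beta >= 1, 1.0, np.nan))
            mid = np.isnan(p)
            if phi > 0:
                a = beta[mid] * (1 - phi) / phi
                b = (1 - beta[mid]) * (1 - phi) / phi
                p[mid] = rng.beta(a, b)
            else:
                p[mid] = beta[mid]
            cov = rng.negative_binomial(
                coverage_size, coverage_size / (coverage_size + coverage_mean), n_sites
            )
            n[:, j] = cov
            x[:, j] = rng.binomial(cov, p)
        return x, n

    x1, n1 = draw(beta1)
    x2, n2 = draw(beta2)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(n_sites) + 1) * spacing,
            "strand": "+",
            "context": context,
        }
    )
    return GroupCounts(sites=sites, x1=x1, n1=n1, x2=x2, n2=n2)


# ---------------------------------------------------------------------------
# fixture emission


def config_hash(config: SyntheticConfig) -> str:
    payload = yaml.safe_dump(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


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


def write_fixture_set(config: SyntheticConfig, outdir: str | Path):
    """Write the complete dataset: CX reports for every stage x replicate,
    genome FASTA, GFF3/BED annotation, truth TSVs and a manifest.

    Returns (genome, features, truth). Identical configs produce identical
    manifest hashes; a failed write removes the partial output.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        genome, features, registry = generate_genome(config)
        truth = build_truth(genome, features, config)
        truth = apply_motif_shifts(truth, registry, config)

        fa = out / "genome.fa"
        with open(fa, "w") as fh:
            for c, seq in genome.items():
                fh.write(f">{c}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        written.append(fa)

        gff = out / "features.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            typemap = {"gene": "gene", "TE": "transposable_element"}
            for _, f in features.iterrows():
                fh.write(
                    f"{f['chrom']}\tsenemeth\t{typemap[f['kind']]}\t{f['start'] + 1}\t{f['end']}\t.\t{f['strand']}\t.\tID={f['id']}\n"
                )
        written.append(gff)
        bed = out / "features.bed"
        write_bed(features, bed)
        written.append(bed)

        sample_files = []
        for stage in config.stages:
            for rep in range(1, config.n_replicates + 1):
                sample, _ = simulate_methylome(genome, features, config, stage, rep, truth)
                p = out / f"{stage}_rep{rep}.CX_report.txt"
                write_cx_report(sample, p)
                written.append(p)
                sample_files.append(p.name)

        for name, df in (
            ("truth_sites.tsv", truth.sites),
            ("truth_planted_regions.tsv", truth.planted_regions),
            ("truth_planted_sites.tsv", truth.planted_sites),
            ("truth_motifs.tsv", truth.motifs),
        ):
            p = out / name
            df.to_csv(p, sep="\t", index=False, lineterminator="\n")
            written.append(p)

        manifest = {
            "config_hash": config_hash(config),
            "rng_seed": int(config.rng_seed),
            "stages": list(config.stages),
            "n_replicates": int(config.n_replicates),
            "samples": sample_files,
            "config": _jsonable(asdict(config)),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return genome, features, truth
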