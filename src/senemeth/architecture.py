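"""Genomic-compartment architecture of methylation change.

Derives promoter windows from gene models, intersects methylation features
with genomic compartments (TEs, ORFs, promoters, intergenic space), and
computes the compartment/stage/context summaries, metagene profiles and
50-bp-bin sample-concordance inputs.

All interval math is 0-based half-open. Two compartment views exist:

* **non-exclusive** membership (a TE inside a gene counts toward both) for
  stage x compartment x context methylation means;
* **exclusive** labels with precedence TE-in-promoter > TE-outside-promoter
  > ORF > promoter-without-TE > intergenic, used for composition fractions.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io import MethylomeSample, bin_weighted_means

__all__ = [
    "COMPARTMENT_LABELS",
    "derive_promoters",
    "merge_intervals",
    "positions_in_intervals",
    "intersect_intervals",
    "closest_interval",
    "assign_compartment",
    "methylation_by_compartment",
    "metagene_profile",
    "sample_concordance",
]

COMPARTMENT_LABELS = (
    "TE_in_promoter",
    "TE_outside_promoter",
    "ORF",
    "promoter_no_TE",
    "intergenic",
)


def derive_promoters(
    genes: pd.DataFrame,
    length: int = 2500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware windows of ``length`` bp immediately upstream of the ATG.

    The ATG is taken at the 5' end of each gene interval; the window ends
    right before it and is clipped at chromosome boundaries (length 0
    windows at a boundary are dropped). Promoters may overlap neighbouring
    features — overlap resolution is the compartment labeller's job.
    """
    if (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "id"].iloc[0]
        raise ValueError(f"gene {bad}: promoter derivation needs a strand")
    starts = np.where(
        genes["strand"] == "+",
        np.maximum(genes["start"] - length, 0),
        genes["end"],
    )
    ends = np.where(genes["strand"] == "+", genes["start"], genes["end"] + length)
    if chrom_lengths is not None:
        lens = genes["chrom"].map(chrom_lengths).to_numpy()
        ends = np.minimum(ends, lens)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "strand": genes["strand"].to_numpy(),
            "kind": "promoter",
            "id": ["prom_" + i for i in genes["id"]],
        }
    )
    return out[out["end"] > out["start"]].reset_index(drop=True)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (overlapping/adjacent runs merged)."""
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def positions_in_intervals(
    chrom: np.ndarray, pos0: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each 0-based position fall inside the interval union."""
    merged = merge_intervals(intervals)
    out = np.zeros(len(pos0), bool)
    for c, sub in merged.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos0[m], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(m.sum(), bool)
        hit[ok] = pos0[m][ok] < ends[idx[ok]]
        out[m] = hit
    return out


def _sorted_or_sort(df: pd.DataFrame, who: str) -> pd.DataFrame:
    s = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not np.array_equal(
        s[["start", "end"]].to_numpy(), df[["start", "end"]].to_numpy()
    ) or not (s["chrom"].to_numpy() == df["chrom"].to_numpy()).all():
        logging.getLogger(__name__).info("%s intervals were not sorted; sorting internally", who)
    return s


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping (a, b) pairs under half-open semantics.

    Returns one row per pair with both ids, both coordinate spans and the
    overlap length (> 0; touching intervals do not overlap).
    """
    a = _sorted_or_sort(a, "a")
    b = _sorted_or_sort(b, "b")
    rows = []
    for chrom, asub in a.groupby("chrom", sort=True):
        bsub = b[b["chrom"] == chrom]
        if bsub.empty:
            continue
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        bid = bsub["id"].to_numpy()
        max_len = int((be - bs).max())
        for _, arow in asub.iterrows():
            a_s, a_e = int(arow["start"]), int(arow["end"])
            hi = np.searchsorted(bs, a_e, side="left")  # b.start < a.end
            lo = np.searchsorted(bs, a_s - max_len, side="left")
            for j in range(lo, hi):
                if be[j] > a_s:
                    ov = min(a_e, be[j]) - max(a_s, bs[j])
                    rows.append(
                        (chrom, arow["id"], a_s, a_e, bid[j], int(bs[j]), int(be[j]), ov)
                    )
    return pd.DataFrame(
        rows,
        columns=["chrom", "a_id", "a_start", "a_end", "b_id", "b_start", "b_end", "overlap"],
    )


def closest_interval(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Nearest b-feature per a-feature with the gap distance.

    The gap between half-open intervals is ``b.start - a.end`` (0 means
    adjacent) on the right, ``a.start - b.end`` on the left; overlap is
    reported as distance 0 with ``overlap=True``. Ties are broken by
    leftmost b start, then lexicographically smallest b id. A-features on
    chromosomes with no b-feature get distance NaN and b_id None.
    """
    a = _sorted_or_sort(a, "a")
    b = _sorted_or_sort(b, "b")
    rows = []
    for chrom, asub in a.groupby("chrom", sort=True):
        bsub = b[b["chrom"] == chrom].sort_values(["start", "id"], kind="mergesort")
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        bid = bsub["id"].to_numpy()
        m = len(bsub)
        pme = np.maximum.accumulate(be) if m else np.empty(0)
        for _, arow in asub.iterrows():
            a_s, a_e = int(arow["start"]), int(arow["end"])
            if m == 0:
                rows.append((chrom, arow["id"], None, np.nan, False))
                continue
            best = None  # (dist, b_start, b_id, overlap)
            j = int(np.searchsorted(bs, a_e, side="left"))
            if j < m:
                best = (int(bs[j] - a_e), int(bs[j]), bid[j], False)
            for i in range(j - 1, -1, -1):
                if best is not None and pme[i] < a_s - best[0]:
                    break  # everything below is strictly farther (no tie possible)
                if be[i] > a_s:
                    cand = (0, int(bs[i]), bid[i], True)
                elif bs[i] >= a_e:
                    cand = (int(bs[i] - a_e), int(bs[i]), bid[i], False)
                else:
                    cand = (int(a_s - be[i]), int(bs[i]), bid[i], False)
                if (
                    best is None
                    or cand[0] < best[0]
                    or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
                ):
                    best = cand
            rows.append((chrom, arow["id"], best[2], best[0], best[3]))
    return pd.DataFrame(rows, columns=["chrom", "a_id", "b_id", "distance", "overlap"])


def assign_compartment(
    chrom: np.ndarray | Sequence[str],
    pos0: np.ndarray | Sequence[int],
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    promoters: pd.DataFrame,
) -> np.ndarray:
    """Exclusive compartment label per 0-based position.

    Precedence: TE inside a promoter window > TE outside promoters > ORF >
    promoter without TE > intergenic. A TE belongs to the in-promoter class
    when its interval overlaps any promoter window.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos0 = np.asarray(pos0, dtype=np.int64)
    lab = np.full(len(pos0), "intergenic", dtype="U22")
    if not promoters.empty:
        lab[positions_in_intervals(chrom, pos0, promoters)] = "promoter_no_TE"
    if not genes.empty:
        lab[positions_in_intervals(chrom, pos0, genes)] = "ORF"
    if not tes.empty:
        te_in_prom_ids = (
            set(intersect_intervals(tes, promoters)["a_id"]) if not promoters.empty else set()
        )
        te_in = tes[tes["id"].isin(te_in_prom_ids)]
        te_out = tes[~tes["id"].isin(te_in_prom_ids)]
        if not te_out.empty:
            lab[positions_in_intervals(chrom, pos0, te_out)] = "TE_outside_promoter"
        if not te_in.empty:
            lab[positions_in_intervals(chrom, pos0, te_in)] = "TE_in_promoter"
    return lab


def assign_compartment_intervals(
    intervals: pd.DataFrame,
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    promoters: pd.DataFrame,
) -> np.ndarray:
    """Exclusive label per interval, decided by the interval midpoint."""
    mid = (intervals["start"].to_numpy() + intervals["end"].to_numpy()) // 2
    return assign_compartment(intervals["chrom"].to_numpy(), mid, genes, tes, promoters)


def methylation_by_compartment(
    samples: Iterable[MethylomeSample],
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    promoters: pd.DataFrame,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Count-weighted mean methylation per (stage, compartment class, context).

    Compartment classes are the non-exclusive {promoter, ORF, TE, total}
    view; contexts include the pooled ``all``. Replicates are averaged
    after per-replicate computation; empty cells are NaN.
    """
    classes = {"promoter": promoters, "ORF": genes, "TE": tes}
    rows = []
    for s in samples:
        df = s.records
        cov = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        meth = df["n_meth"].to_numpy()
        chrom = df["chrom"].to_numpy(dtype=object)
        pos0 = df["pos"].to_numpy() - 1
        ctx = df["context"].to_numpy()
        masks = {name: positions_in_intervals(chrom, pos0, iv) if len(iv) else np.zeros(len(df), bool)
                 for name, iv in classes.items()}
        masks["total"] = np.ones(len(df), bool)
        for name, m in masks.items():
            for c in list(contexts) + ["all"]:
                sel = m if c == "all" else m & (ctx == c)
                tot = cov[sel].sum()
                val = meth[sel].sum() / tot if tot > 0 else np.nan
                rows.append((s.stage, s.replicate, name, c, val, int(tot)))
    per_rep = pd.DataFrame(
        rows, columns=["stage", "replicate", "compartment", "context", "mean_meth", "n_reads"]
    )
    out = (
        per_rep.groupby(["stage", "compartment", "context"], sort=False)["mean_meth"]
        .mean()
        .reset_index()
    )
    return out


def metagene_profile(
    samples: Iterable[MethylomeSample],
    genes: pd.DataFrame,
    flank: int = 1000,
    min_gene_len: int = 400,
    body_bins: int = 20,
    flank_bin: int = 50,
) -> pd.DataFrame:
    """Mean methylation along genes and their flanks, strand-oriented.

    Genes strictly longer than ``min_gene_len`` contribute. Flanks are cut
    into absolute ``flank_bin``-bp bins, the gene body into ``body_bins``
    equal relative bins; minus-strand genes are reversed so bin 0 is always
    the 5' end. The profile is the unweighted mean over genes of per-gene
    count-weighted bin methylation. Returns a tidy frame with (stage,
    context, bin, region, mean_meth, n_genes).
    """
    if flank % flank_bin:
        raise ValueError("flank must be divisible by flank_bin")
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    genes = genes[(genes["end"] - genes["start"]) > min_gene_len]
    if (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("metagene profile needs stranded genes")

    # pool replicate counts per stage
    by_stage: dict[str, list[MethylomeSample]] = {}
    for s in samples:
        by_stage.setdefault(s.stage, []).append(s)

    rows = []
    for stage, reps in by_stage.items():
        pooled = pd.concat([r.records for r in reps], ignore_index=True)
        cov = pooled["n_meth"] + pooled["n_unmeth"]
        pooled = pooled.loc[cov > 0]
        for context, cdf in pooled.groupby("context"):
            if context not in ("CG", "CHG", "CHH"):
                continue
            meth_sum = np.zeros((len(genes), n_bins))
            cov_sum = np.zeros((len(genes), n_bins))
            for chrom, sub in cdf.groupby("chrom"):
                sub = sub.sort_values("pos", kind="mergesort")
                pos0 = sub["pos"].to_numpy() - 1
                meth = sub["n_meth"].to_numpy(dtype=float)
                c = (sub["n_meth"] + sub["n_unmeth"]).to_numpy(dtype=float)
                gsub = genes[genes["chrom"] == chrom]
                for gi, g in zip(np.flatnonzero((genes["chrom"] == chrom).to_numpy()), gsub.itertuples()):
                    lo, hi = g.start - flank, g.end + flank
                    i0, i1 = np.searchsorted(pos0, [lo, hi])
                    p = pos0[i0:i1]
                    if len(p) == 0:
                        continue
                    rel = np.empty(len(p))
                    up = p < g.start
                    down = p >= g.end
                    body = ~up & ~down
                    binidx = np.empty(len(p), dtype=int)
                    binidx[up] = (p[up] - lo) // flank_bin
                    glen = g.end - g.start
                    binidx[body] = n_flank + np.minimum(
                        (p[body] - g.start) * body_bins // glen, body_bins - 1
                    )
                    binidx[down] = n_flank + body_bins + (p[down] - g.end) // flank_bin
                    if g.strand == "-":
                        binidx = n_bins - 1 - binidx
                    np.add.at(meth_sum[gi], binidx, meth[i0:i1])
                    np.add.at(cov_sum[gi], binidx, c[i0:i1])
            with np.errstate(invalid="ignore", divide="ignore"):
                per_gene = np.where(cov_sum > 0, meth_sum / np.maximum(cov_sum, 1e-300), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                prof = np.nanmean(per_gene, axis=0)
            n_genes = np.sum(~np.isnan(per_gene), axis=0)
            for bi in range(n_bins):
                region = (
                    "upstream" if bi < n_flank
                    else "body" if bi < n_flank + body_bins
                    else "downstream"
                )
                rows.append((stage, context, bi, region, prof[bi], int(n_genes[bi])))
    return pd.DataFrame(rows, columns=["stage", "context", "bin", "region", "mean_meth", "n_genes"])


def sample_concordance(
    samples: Sequence[MethylomeSample],
    bin_size: int = 50,
    context: str | None = None,
):
    """Manhattan distance matrix and PCA scores over per-bin weighted means.

    Bins missing (uncovered) in any sample are dropped listwise before the
    distances. The principal components are those of the centred (not
    scaled) bin matrix. Returns ``(distances, scores, explained_ratio)``.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mat = bin_weighted_means(samples, bin_size=bin_size, context=context)
    mat = mat.dropna(axis=0, how="any")
    if mat.shape[0] < 2:
        raise ValueError("fewer than two bins shared by all samples")
    X = mat.to_numpy().T  # samples x bins
    labels = list(mat.columns)
    d = squareform(pdist(X, metric="cityblock"))
    dist = pd.DataFrame(d, index=labels, columns=labels)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = pd.DataFrame(
        u * sv, index=labels, columns=[f"PC{i + 1}" for i in range(len(sv))]
    )
    var = sv**2
    explained = var / var.sum() if var.sum() > 0 else var
    return dist, scores, explained
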