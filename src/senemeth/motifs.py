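"""Transcription-factor binding-site methylation analysis.

Locates binding motifs (the WRKY W-box TTGACT/TTGACC and the palindromic
bZIP A-/C-/G-boxes TACGTA/GACGTC/CACGTG), classifies their cytosines by
sequence context from the genome, compares motif-cytosine methylation with
compartment-matched genomic background through an empirical bootstrap, and
counts motif/DML/DMR coincidences.

The bootstrap null: draw B random subsets of the background, each of the
same size as the motif-cytosine set and drawn without replacement, and take
the fraction of null means at least as extreme as the observed mean (in the
observed direction, with the add-one correction ``p = (1 + #extreme) /
(B + 1)``) as the P-value estimate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylomeSample, revcomp

__all__ = [
    "MotifDef",
    "DEFAULT_MOTIFS",
    "scan_motifs",
    "motif_cytosines",
    "motif_methylation_summary",
    "bootstrap_motif_test",
    "BootstrapResult",
    "count_dml_in_motifs",
    "count_motifs_in_dmrs",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC motif and how to scan it.

    ``scan_strands`` is ``both`` (reverse-complement hits reported on the
    minus strand in reference coordinates) or ``forward``; palindromic
    patterns are deduplicated to one occurrence per position either way.
    """

    name: str
    patterns: tuple[str, ...]
    scan_strands: str = "both"

    def __post_init__(self):
        for p in self.patterns:
            if len(p) < 4:
                raise ValueError(f"{self.name}: pattern {p!r} shorter than 4")
            if not set(p) <= set(_IUPAC):
                raise ValueError(f"{self.name}: non-IUPAC letters in {p!r}")
        if self.scan_strands not in ("both", "forward"):
            raise ValueError("scan_strands must be 'both' or 'forward'")

    @property
    def family(self) -> str:
        return "W-box" if self.name == "W-box" else "bZIP"


DEFAULT_MOTIFS = (
    MotifDef("W-box", ("TTGACT", "TTGACC")),
    MotifDef("A-box", ("TACGTA",)),
    MotifDef("C-box", ("GACGTC",)),
    MotifDef("G-box", ("CACGTG",)),
)


def _regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    return re.compile("(?=(" + "".join(_IUPAC[c] for c in pattern) + "))")


def scan_motifs(
    genome: dict[str, str], motifs=DEFAULT_MOTIFS
) -> pd.DataFrame:
    """All match positions of each motif over the genome.

    Returns a 0-based half-open interval table (chrom, start, end, strand,
    motif, pattern). Minus-strand rows are matches of the reverse
    complement, mapped to reference coordinates; exact palindromes are
    reported once, on the plus strand.
    """
    rows = []
    for motif in motifs:
        if not motif.patterns:
            raise ValueError(f"{motif.name}: empty pattern list")
        for pat in motif.patterns:
            rx = _regex(pat)
            is_palindrome = revcomp(pat) == pat
            for chrom, seq in genome.items():
                for m in rx.finditer(seq):
                    rows.append((chrom, m.start(1), m.end(1), "+", motif.name, pat))
                if motif.scan_strands == "both" and not is_palindrome:
                    rc = revcomp(pat)
                    for m in _regex(rc).finditer(seq):
                        rows.append((chrom, m.start(1), m.end(1), "-", motif.name, pat))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "motif", "pattern"])
    out = out.sort_values(["chrom", "start", "motif", "strand"], kind="mergesort")
    return out.reset_index(drop=True)


def motif_cytosines(occurrences: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Member cytosines (both strands) of every motif occurrence.

    Each reference C inside the interval is a plus-strand cytosine, each G
    a minus-strand one; contexts are derived from the genome so e.g. the
    W-box C of TTGACTG reads CHG while TTGACTA reads CHH.
    """
    from .io import derive_context

    rows = []
    for occ in occurrences.itertuples():
        seq = genome[occ.chrom]
        for p0 in range(occ.start, occ.end):
            base = seq[p0]
            if base == "C":
                ctx = derive_context(genome, occ.chrom, p0 + 1, "+")
                rows.append((occ.chrom, p0 + 1, "+", ctx, occ.motif, occ.Index))
            elif base == "G":
                ctx = derive_context(genome, occ.chrom, p0 + 1, "-")
                rows.append((occ.chrom, p0 + 1, "-", ctx, occ.motif, occ.Index))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "motif", "occurrence"]
    )


def motif_methylation_summary(
    cytosines: pd.DataFrame,
    samples: list[MethylomeSample],
    compartment_of: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Mean methylation of motif cytosines per (stage, compartment, context, motif).

    ``compartment_of`` labels each cytosine row. Each covered cytosine
    contributes its replicate-mean beta once; sites are averaged unweighted
    (site-level means, not read-weighted). Uncovered cytosines are skipped;
    empty cells are NaN.
    """
    cyt = cytosines.copy()
    cyt["compartment"] = np.asarray(compartment_of)
    by_stage: dict[str, list[MethylomeSample]] = {}
    for s in samples:
        by_stage.setdefault(s.stage, []).append(s)
    rows = []
    for stage, reps in by_stage.items():
        beta_frames = []
        for r in reps:
            df = r.records
            cov = df["n_meth"] + df["n_unmeth"]
            sub = df.loc[cov > 0, ["chrom", "pos", "strand"]].copy()
            sub["beta"] = (df.loc[cov > 0, "n_meth"] / cov[cov > 0]).to_numpy()
            beta_frames.append(sub)
        pooled = pd.concat(beta_frames, ignore_index=True)
        site_beta = pooled.groupby(["chrom", "pos", "strand"])["beta"].mean()
        joined = cyt.join(site_beta, on=["chrom", "pos", "strand"], how="inner")
        g = joined.groupby(["compartment", "context", "motif"])["beta"]
        for (comp, ctx, motif), vals in g:
            rows.append((stage, comp, ctx, motif, float(vals.mean()), len(vals)))
    return pd.DataFrame(
        rows, columns=["stage", "compartment", "context", "motif", "mean_meth", "n_sites"]
    )


@dataclass
class BootstrapResult:
    """Outcome of one motif-vs-background bootstrap comparison."""

    observed_mean: float
    n_motif_cytosines: int
    n_background: int
    n_draws: int
    null_mean: float
    null_sd: float
    p_estimate: float
    direction: str
    two_sided: bool = False


def _null_means(values: np.ndarray, n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """Means of B size-n draws without replacement, vectorised in chunks.

    The background is sorted first so the draw sequence depends only on the
    multiset of values: the P estimate is invariant to background order.
    """
    values = np.sort(values)
    N = len(values)
    out = np.empty(B)
    # random keys + argpartition = B independent simple random samples
    chunk = max(1, int(4e6 // max(N, 1)))
    done = 0
    while done < B:
        c = min(chunk, B - done)
        keys = rng.random((c, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[done : done + c] = values[idx].mean(axis=1)
        done += c
    return out


def bootstrap_motif_test(
    motif_values: np.ndarray,
    background_values: np.ndarray,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    two_sided: bool = False,
    direction: str | None = None,
) -> BootstrapResult:
    """Empirical P of the motif-set mean against matched background.

    Draws ``B`` random samples of the motif-set size from the background
    without replacement; the P estimate is the add-one-corrected fraction
    of null means at least as extreme as the observed mean, one-sided in
    the observed direction (doubled and capped at 1 when ``two_sided``).
    Passing ``direction`` (``"up"`` or ``"down"``) fixes the tested tail in
    advance, the pre-registered form under which null p-values are uniform.
    """
    motif_values = np.asarray(motif_values, dtype=float)
    background_values = np.asarray(background_values, dtype=float)
    n = len(motif_values)
    if n == 0:
        raise ValueError("empty motif set")
    if len(background_values) < n:
        raise ValueError(
            "background smaller than motif set; pool compartments or contexts"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = float(motif_values.mean())
    null = _null_means(background_values, n, B, rng)
    null_mean = float(null.mean())
    if direction is None:
        direction = "up" if obs >= null_mean else "down"
    elif direction not in ("up", "down"):
        raise ValueError("direction must be 'up', 'down' or None")
    if direction == "up":
        extreme = int((null >= obs).sum())
    else:
        extreme = int((null <= obs).sum())
    p = (1 + extreme) / (B + 1)
    if two_sided:
        p = min(1.0, 2 * p)
    return BootstrapResult(
        observed_mean=obs,
        n_motif_cytosines=n,
        n_background=len(background_values),
        n_draws=B,
        null_mean=null_mean,
        null_sd=float(null.std()),
        p_estimate=p,
        direction=direction,
        two_sided=two_sided,
    )


def count_dml_in_motifs(
    dmls: pd.DataFrame, occurrences: pd.DataFrame
) -> pd.DataFrame:
    """DMLs whose cytosine lies inside a motif interval, per motif name.

    Positions are 1-based; an occurrence covers 0-based [start, end), i.e.
    1-based start+1 .. end. Returns per-motif DML counts, occurrence
    totals, and the fraction of motif instances hit by at least one DML.
    """
    rows = []
    for motif, occ in occurrences.groupby("motif"):
        hit_occ: set = set()
        n_dml = 0
        for chrom, osub in occ.groupby("chrom"):
            d = dmls[dmls["chrom"] == chrom]
            if d.empty:
                continue
            starts = osub["start"].to_numpy()
            ends = osub["end"].to_numpy()
            oidx = osub.index.to_numpy()
            order = np.argsort(starts)
            starts, ends, oidx = starts[order], ends[order], oidx[order]
            pos0 = d["pos"].to_numpy() - 1
            # motifs are short and same-length per family: bounded scan
            max_len = int((ends - starts).max())
            j = np.searchsorted(starts, pos0, side="right")
            for p, jj in zip(pos0, j):
                for k in range(jj - 1, -1, -1):
                    if starts[k] <= p - max_len:
                        break
                    if starts[k] <= p < ends[k]:
                        n_dml += 1
                        hit_occ.add(oidx[k])
            # a DML inside two overlapping instances of the same motif counts once per instance
        rows.append((motif, n_dml, len(occ), len(hit_occ), len(hit_occ) / len(occ) if len(occ) else np.nan))
    return pd.DataFrame(
        rows, columns=["motif", "n_dml_in_motif", "n_occurrences", "n_occurrences_hit", "fraction_hit"]
    )


def count_motifs_in_dmrs(
    dmrs: pd.DataFrame,
    occurrences: pd.DataFrame,
    promoters: pd.DataFrame,
    tes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Motif instances fully contained in DMRs that intersect promoters.

    Returns one row per (DMR, motif) with the count of contained
    occurrences, plus a flag when the DMR also overlaps a TE (the
    TE-in-promoter neighbourhood the W-box analysis highlights).
    """
    from .architecture import intersect_intervals

    if dmrs.empty:
        return pd.DataFrame(
            columns=["dmr_id", "chrom", "start", "end", "motif", "n_motifs", "overlaps_te"]
        )
    d = dmrs.copy().reset_index(drop=True)
    if "id" not in d:
        d["id"] = [f"dmr{i:05d}" for i in range(len(d))]
    prom_hits = intersect_intervals(d, promoters)
    keep = set(prom_hits["a_id"])
    d = d[d["id"].isin(keep)].reset_index(drop=True)
    te_ids: set = set()
    if tes is not None and not tes.empty and not d.empty:
        te_ids = set(intersect_intervals(d, tes)["a_id"])
    rows = []
    for dmr in d.itertuples():
        occ = occurrences[
            (occurrences["chrom"] == dmr.chrom)
            & (occurrences["start"] >= dmr.start)
            & (occurrences["end"] <= dmr.end)
        ]
        for motif, osub in occ.groupby("motif"):
            rows.append(
                (dmr.id, dmr.chrom, dmr.start, dmr.end, motif, len(osub), dmr.id in te_ids)
            )
    return pd.DataFrame(
        rows, columns=["dmr_id", "chrom", "start", "end", "motif", "n_motifs", "overlaps_te"]
    )
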