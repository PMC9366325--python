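"""Reading, writing and per-cytosine preprocessing of methylome data.

The pipeline speaks two coordinate dialects and this module is the only
place where they meet:

* per-cytosine records use **1-based** positions on the cytosine's strand,
  the convention of Bismark ``--CX --cytosine_report`` output;
* all interval arithmetic (genes, TEs, promoters, DMRs, motifs, bins) uses
  **0-based half-open** coordinates, the BED convention.

A methylome sample is held as a :class:`pandas.DataFrame` with one row per
cytosine; :class:`MethylomeSample` wraps it with its stage/replicate labels.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CX_COLUMNS",
    "MethylomeSample",
    "read_genome",
    "read_cx_report",
    "write_cx_report",
    "derive_context",
    "derive_contexts_vectorized",
    "filter_coverage",
    "bin_weighted_means",
    "read_features",
    "read_bed",
    "write_bed",
    "gff_to_intervals",
]

#: Column order of a Bismark CX cytosine report.
CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Columns of the interval (feature) table; coordinates 0-based half-open.
INTERVAL_COLUMNS = ["chrom", "start", "end", "strand", "kind", "id"]


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MethylomeSample:
    """Per-cytosine methylation counts for one sample.

    Parameters
    ----------
    stage
        Developmental stage label (``Blt``, ``Flwr``, ``SD``, ``SM`` in the
        senescence design, but any label is accepted).
    replicate
        Replicate identifier.
    records
        DataFrame with :data:`CX_COLUMNS`, sorted by (chrom, pos).
    """

    stage: str
    replicate: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CX_COLUMNS))

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns[: len(CX_COLUMNS)]) != CX_COLUMNS:
            raise ValueError(f"records must have columns {CX_COLUMNS}")
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos, strand) records")
        if not df.empty:
            order = df.sort_values(["chrom", "pos"], kind="mergesort").index
            if not np.array_equal(order.to_numpy(), df.index.to_numpy()):
                self.records = df.loc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coverage(self) -> pd.Series:
        return self.records["n_meth"] + self.records["n_unmeth"]

    @property
    def beta(self) -> pd.Series:
        """Per-site methylation level m/(m+u); NaN where coverage is 0."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.records["n_meth"] / cov
        return b.where(cov > 0)

    def label(self) -> str:
        return f"{self.stage}_{self.replicate}"


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into an upper-case {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def derive_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Classify the cytosine at 1-based ``pos`` into CG / CHG / CHH / NA.

    The two bases 3' of the cytosine *on its own strand* decide the context
    (H = A, C or T): CG if the next base is G, CHG if the second is G, CHH if
    both are H. Fewer than two downstream bases, or any N among them, gives
    NA. Raises ``ValueError`` if the strand base at ``pos`` is not C.
    """
    seq = genome[chrom]
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[i]!r}, not C")
        down = seq[i + 1 : i + 3]
    elif strand == "-":
        if seq[i] != "G":  # C on the minus strand reads G on the reference
            raise ValueError(f"{chrom}:{pos}(-) is {seq[i]!r} on +, not G")
        down = revcomp(seq[max(i - 2, 0) : i])
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if len(down) < 2 or "N" in down:
        return "NA"
    if down[0] == "G":
        return "CG"
    if down[1] == "G":
        return "CHG"
    return "CHH"


def derive_contexts_vectorized(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosine sites of one chromosome, both strands, as arrays.

    Returns ``(pos, strand, context)`` where ``pos`` is 1-based, ``strand``
    is ``+``/``-`` and ``context`` is one of CG/CHG/CHH/NA. Plus-strand sites
    are C's on the reference; minus-strand sites are G's.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_n = arr == b"N"
    is_h = ~is_g & ~is_n  # A, C or T

    def classify(idx: np.ndarray, d1_g, d1_h, d2_g, d2_ok, valid) -> np.ndarray:
        ctx = np.full(len(idx), "NA", dtype="U3")
        ctx[valid & d1_g] = "CG"
        ctx[valid & d1_h & d2_g] = "CHG"
        ctx[valid & d1_h & ~d2_g & d2_ok] = "CHH"
        return ctx

    # plus strand: downstream = i+1, i+2
    ip = np.flatnonzero(is_c)
    ok1 = ip + 1 < n
    ok2 = ip + 2 < n
    d1g = np.zeros(len(ip), bool)
    d1h = np.zeros(len(ip), bool)
    d2g = np.zeros(len(ip), bool)
    d2ok = np.zeros(len(ip), bool)
    d1g[ok1] = is_g[ip[ok1] + 1]
    d1h[ok1] = is_h[ip[ok1] + 1]
    d2g[ok2] = is_g[ip[ok2] + 2]
    d2ok[ok2] = ~is_n[ip[ok2] + 2]
    # two downstream bases must exist and be unambiguous, even for CG
    ctx_p = classify(ip, d1g, d1h, d2g, d2ok, ok2 & (d1g | d1h) & d2ok)
    # minus strand: downstream on - strand = i-1, i-2 on reference, complemented.
    im = np.flatnonzero(is_g)
    ok1 = im - 1 >= 0
    ok2 = im - 2 >= 0
    d1g = np.zeros(len(im), bool)
    d1h = np.zeros(len(im), bool)
    d2g = np.zeros(len(im), bool)
    d2ok = np.zeros(len(im), bool)
    # complement: reference C reads G on minus strand, reference G reads C (an H)
    d1g[ok1] = is_c[im[ok1] - 1]
    d1h[ok1] = ~is_c[im[ok1] - 1] & ~is_n[im[ok1] - 1]
    d2g[ok2] = is_c[im[ok2] - 2]
    d2ok[ok2] = ~is_n[im[ok2] - 2]
    ctx_m = classify(im, d1g, d1h, d2g, d2ok, ok2 & (d1g | d1h) & d2ok)

    pos = np.concatenate([ip, im]) + 1
    strand = np.concatenate([np.full(len(ip), "+"), np.full(len(im), "-")])
    ctx = np.concatenate([ctx_p, ctx_m])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], ctx[order]


def trinucleotide_at(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """3-mer starting at the cytosine on its own strand, N-padded at ends."""
    seq = genome[chrom]
    i = pos - 1
    if strand == "+":
        tri = seq[i : i + 3]
        return tri + "N" * (3 - len(tri))
    tri = revcomp(seq[max(i - 2, 0) : i + 1])
    return tri + "N" * (3 - len(tri))


def read_cx_report(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
    stage: str = "",
    replicate: str = "",
) -> MethylomeSample:
    """Parse a Bismark CX cytosine report (7-column TSV).

    If ``genome`` is given, the sequence context of every record is
    re-derived from it and stored in a ``context_mismatch`` boolean column
    so discrepancies with the file's context column are auditable.
    """
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            header=None,
            comment=None,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CX_COLUMNS)
    if not df.empty:
        for col in ("pos", "n_meth", "n_unmeth"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                lineno = int(vals.isna().idxmax()) + 1
                raise ValueError(f"{path}: malformed line {lineno}: non-numeric {col}")
            df[col] = vals.astype(np.int64)
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: line {lineno}: unknown strand symbol {df['strand'][lineno - 1]!r}")
        if df.shape[1] != len(CX_COLUMNS) or df[CX_COLUMNS[-1]].isna().any():
            lineno = int(df[CX_COLUMNS[-1]].isna().idxmax()) + 1
            raise ValueError(f"{path}: malformed line {lineno}: expected 7 columns")
        if genome is not None:
            derived = [
                derive_context(genome, c, int(p), s)
                for c, p, s in zip(df["chrom"], df["pos"], df["strand"])
            ]
            df["context_derived"] = derived
            df["context_mismatch"] = df["context_derived"] != df["context"]
    return MethylomeSample(stage=stage, replicate=replicate, records=df)


def write_cx_report(sample: MethylomeSample, path: str | Path) -> None:
    """Write a sample back out as a 7-column CX report (deterministic order)."""
    sample.records.loc[:, CX_COLUMNS].to_csv(
        str(path), sep="\t", header=False, index=False, lineterminator="\n"
    )


def filter_coverage(sample: MethylomeSample, min_cov: int = 3, max_cov: int = 40) -> MethylomeSample:
    """Keep records whose coverage lies in ``[min_cov, max_cov]`` (inclusive).

    The inclusive bounds are the literal complement of removing sites with
    coverage <3 or >40. Order is preserved; the operation is idempotent.
    """
    if min_cov > max_cov:
        raise ValueError(f"min_cov {min_cov} > max_cov {max_cov}")
    cov = sample.coverage
    keep = (cov >= min_cov) & (cov <= max_cov)
    return MethylomeSample(
        stage=sample.stage,
        replicate=sample.replicate,
        records=sample.records.loc[keep].reset_index(drop=True),
    )


def bin_weighted_means(
    samples: Iterable[MethylomeSample],
    bin_size: int = 50,
    context: str | None = None,
) -> pd.DataFrame:
    """Count-weighted mean methylation of fixed-width genomic bins.

    Each bin value is Σ n_meth / Σ (n_meth + n_unmeth) over the cytosines
    falling in the bin (both strands pooled); bins with no covered cytosine
    in a sample are NaN, *not* zero. Rows are indexed by (chrom, bin_start);
    one column per sample label.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    cols = {}
    for s in samples:
        df = s.records
        if context is not None:
            df = df[df["context"] == context]
        cov = df["n_meth"] + df["n_unmeth"]
        df = df.loc[cov > 0]
        key = pd.MultiIndex.from_arrays(
            [df["chrom"], (df["pos"] - 1) // bin_size * bin_size],
            names=["chrom", "bin_start"],
        )
        g = df.groupby(key)[["n_meth", "n_unmeth"]].sum()
        cols[s.label()] = g["n_meth"] / (g["n_meth"] + g["n_unmeth"])
    out = pd.DataFrame(cols)
    return out.sort_index()


# ---------------------------------------------------------------------------
# Feature (interval) I/O


def gff_to_intervals(gff: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """Convert GFF3 1-based inclusive rows to 0-based half-open intervals."""
    ids = gff["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    ids = ids.fillna(pd.Series([f"feat{i}" for i in range(len(gff))], index=gff.index))
    out = pd.DataFrame(
        {
            "chrom": gff["seqid"].astype(str),
            "start": gff["start"].astype(np.int64) - 1,
            "end": gff["end"].astype(np.int64),
            "strand": gff["strand"].astype(str),
            "kind": kind if kind is not None else gff["type"].astype(str),
            "id": ids.astype(str),
        }
    )
    bad = out["end"] < out["start"]
    if bad.any():
        raise ValueError(f"feature {out.loc[bad, 'id'].iloc[0]}: end < start after conversion")
    return out.reset_index(drop=True)


def read_features(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    """Read gene/TE features from GFF3 or BED into the interval table.

    The format is chosen by extension (.gff/.gff3 vs .bed). GFF3 rows may be
    filtered by ``kind`` matching the GFF ``type`` column; the returned
    ``kind`` column is overwritten with ``kind`` when given.
    """
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        gff = pd.read_csv(
            p,
            sep="\t",
            comment="#",
            header=None,
            names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
            dtype={"seqid": str, "attributes": str},
        )
        if kind is not None:
            gff = gff[gff["type"] == kind].reset_index(drop=True)
        return gff_to_intervals(gff, kind=kind)
    return read_bed(p, kind=kind or "feature")


def read_bed(path: str | Path, kind: str = "feature") -> pd.DataFrame:
    """Read a BED3/BED6 file (already 0-based half-open)."""
    bed = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype={0: str})
    ncol = bed.shape[1]
    out = pd.DataFrame(
        {
            "chrom": bed[0].astype(str),
            "start": bed[1].astype(np.int64),
            "end": bed[2].astype(np.int64),
            "strand": bed[5].astype(str) if ncol >= 6 else ".",
            "kind": kind,
            "id": bed[3].astype(str) if ncol >= 4 else [f"{kind}{i}" for i in range(len(bed))],
        }
    )
    bad = out["end"] < out["start"]
    if bad.any():
        raise ValueError(f"feature {out.loc[bad, 'id'].iloc[0]}: end < start")
    return out


def write_bed(intervals: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """Write intervals as BED6 (+ optional extra columns), newline-terminated."""
    df = intervals.copy()
    cols = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "name": df["id"] if "id" in df else ".",
            "score": df["score"] if "score" in df else 0,
            "strand": df["strand"] if "strand" in df else ".",
        }
    )
    for c in extra_cols or []:
        cols[c] = df[c]
    buf = _io.StringIO()
    cols.to_csv(buf, sep="\t", header=False, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())
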