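"""Beta-binomial differential methylation calling between stage groups.

Per-cytosine two-group comparison with replicate overdispersion, DML
calling at a minimum effect size via the posterior tail probability, and
DMR aggregation of significant-site runs.

The site test models methylated counts ``X_gj ~ BetaBinomial(N_gj, mu_g,
phi)``: the group mean is the pooled proportion ``mu_g = sum X / sum N``
with variance

    Var(mu_g) = sum_j N_gj mu_g (1 - mu_g) (1 + (N_gj - 1) phi) / (sum_j N_gj)^2

and the Wald statistic ``z = (mu_1 - mu_2) / sqrt(Var_1 + Var_2)`` is
referred to the standard normal. A locus is a DML when the posterior
probability that the true |difference| exceeds ``delta`` (0.25 by default,
i.e. a 25% methylation change) is at least ``1 - p_threshold``, taking the
difference as Normal(diff, se^2). No multiple-testing correction is applied
by default; Benjamini-Hochberg is available as an option.

Dispersion is estimated per site by the method of moments and shrunk
toward a context-wide trimmed mean, a lightweight stand-in for a full
hierarchical fit that behaves correctly in the two regimes that matter:
zero replicate scatter collapses to the lower clip, and unreplicated sites
inherit the genome-wide prior exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylomeSample

__all__ = [
    "GroupCounts",
    "build_group_counts",
    "estimate_dispersion",
    "dml_test",
    "call_dml",
    "call_dmr",
    "summarize_dml",
]

logger = logging.getLogger(__name__)

PHI_CLIP = (1e-4, 0.5)


@dataclass
class GroupCounts:
    """Aligned per-site replicate count matrices for a two-group comparison.

    ``sites`` has one row per (chrom, pos, strand) with its context;
    ``x1/n1`` and ``x2/n2`` are (site x replicate) methylated/total count
    matrices with zeros where a replicate did not cover the site.
    """

    sites: pd.DataFrame
    x1: np.ndarray
    n1: np.ndarray
    x2: np.ndarray
    n2: np.ndarray

    def __len__(self) -> int:
        return len(self.sites)


_KEY = ["chrom", "pos", "strand"]


def build_group_counts(
    group1: list[MethylomeSample], group2: list[MethylomeSample]
) -> GroupCounts:
    """Outer-join replicates of both groups on the site key."""
    def frame(s: MethylomeSample, tag: str) -> pd.DataFrame:
        df = s.records[_KEY + ["context", "n_meth", "n_unmeth"]].copy()
        df[tag + "_n"] = df["n_meth"] + df["n_unmeth"]
        return df.rename(columns={"n_meth": tag + "_x"}).drop(columns=["n_unmeth"])

    merged: pd.DataFrame | None = None
    tags1, tags2 = [], []
    for g, samples, tags in ((1, group1, tags1), (2, group2, tags2)):
        for j, s in enumerate(samples):
            tag = f"g{g}r{j}"
            tags.append(tag)
            f = frame(s, tag)
            if merged is None:
                merged = f
            else:
                merged = merged.merge(
                    f, on=_KEY + ["context"], how="outer", sort=False
                )
    assert merged is not None
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    x1 = merged[[t + "_x" for t in tags1]].fillna(0).to_numpy(dtype=float)
    n1 = merged[[t + "_n" for t in tags1]].fillna(0).to_numpy(dtype=float)
    x2 = merged[[t + "_x" for t in tags2]].fillna(0).to_numpy(dtype=float)
    n2 = merged[[t + "_n" for t in tags2]].fillna(0).to_numpy(dtype=float)
    return GroupCounts(sites=merged[_KEY + ["context"]].copy(), x1=x1, n1=n1, x2=x2, n2=n2)


def _site_moment_phi(x: np.ndarray, n: np.ndarray):
    """Per-site method-of-moments dispersion contribution of one group.

    Returns (phi_numerator-style estimate, residual df, replicate count).
    Sites with <2 covered replicates contribute df 0.
    """
    covered = n > 0
    m = covered.sum(axis=1)
    tot = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(tot > 0, x.sum(axis=1) / np.maximum(tot, 1), np.nan)
        p = np.where(covered, x / np.maximum(n, 1), np.nan)
    dev = (p - mu[:, None]) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s2 = np.nansum(dev, axis=1) / np.maximum(m - 1, 1)
        inv_n = np.nansum(np.where(covered, 1.0 / np.maximum(n, 1), np.nan), axis=1) / np.maximum(m, 1)
    v = mu * (1 - mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (s2 / v - inv_n) / np.maximum(1 - inv_n, 1e-12)
    phi = np.where((m >= 2) & (v > 0), phi, np.nan)
    phi = np.where((m >= 2) & (v == 0), 0.0, phi)  # identical degenerate proportions
    df = np.maximum(m - 1, 0)
    return phi, df, m


def estimate_dispersion(counts: GroupCounts, k: float = 4.0) -> np.ndarray:
    """Shrunken per-site beta-binomial dispersion.

    The raw site estimate pools the two groups' moment estimates (weighted
    by residual degrees of freedom) and is shrunk toward the context-wide
    20%-trimmed mean with weight ``w = m / (m + k)`` where ``m`` is the
    number of covered replicates at the site. Estimates are clipped to
    ``[1e-4, 0.5]``. With no replicated site anywhere, falls back to the
    pooled-binomial floor with a warning.
    """
    phi1, df1, m1 = _site_moment_phi(counts.x1, counts.n1)
    phi2, df2, m2 = _site_moment_phi(counts.x2, counts.n2)
    df_tot = df1 + df2
    with np.errstate(invalid="ignore"):
        num = np.where(np.isnan(phi1), 0, phi1 * df1) + np.where(np.isnan(phi2), 0, phi2 * df2)
        phi_site = np.where(df_tot > 0, num / np.maximum(df_tot, 1), np.nan)
    phi_site_cl = np.clip(phi_site, 0.0, PHI_CLIP[1])

    ctx = counts.sites["context"].to_numpy()
    prior = np.full(len(ctx), np.nan)
    for c in pd.unique(ctx):
        sel = (ctx == c) & ~np.isnan(phi_site_cl)
        if sel.sum() > 0:
            prior[ctx == c] = stats.trim_mean(phi_site_cl[sel], 0.2)
    if np.isnan(prior).all():
        logger.warning("no replicated sites; falling back to pooled binomial dispersion")
        return np.full(len(ctx), PHI_CLIP[0])
    # contexts without any replicated site borrow the global prior
    global_prior = stats.trim_mean(phi_site_cl[~np.isnan(phi_site_cl)], 0.2)
    prior = np.where(np.isnan(prior), global_prior, prior)

    m = m1 + m2
    w = m / (m + k)
    phi_hat = np.where(
        df_tot > 0, w * phi_site_cl + (1 - w) * prior, prior
    )
    return np.clip(phi_hat, PHI_CLIP[0], PHI_CLIP[1])


def dml_test(counts: GroupCounts, phi: np.ndarray | float) -> pd.DataFrame:
    """Per-site beta-binomial Wald test.

    Sites with zero total coverage in either group are skipped (logged).
    Returns one row per testable site with mu1, mu2, diff, se_diff, wald_z
    and the two-sided p; zero-variance ties give z = 0, p = 1.
    """
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (len(counts),))
    t1 = counts.n1.sum(axis=1)
    t2 = counts.n2.sum(axis=1)
    testable = (t1 > 0) & (t2 > 0)
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info("dml_test: skipped %d sites with zero coverage in a group", n_skip)

    def group_stats(x, n, tot):
        mu = x.sum(axis=1) / np.maximum(tot, 1)
        var = (n * (mu * (1 - mu))[:, None] * (1 + (n - 1) * phi[:, None])).sum(axis=1)
        return mu, var / np.maximum(tot, 1) ** 2

    mu1, v1 = group_stats(counts.x1, counts.n1, t1)
    mu2, v2 = group_stats(counts.x2, counts.n2, t2)
    diff = mu1 - mu2
    se = np.sqrt(v1 + v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1), 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    out = counts.sites.copy()
    out["mu1"], out["mu2"], out["diff"] = mu1, mu2, diff
    out["se_diff"], out["wald_z"], out["p_raw"] = se, z, p
    return out.loc[testable].reset_index(drop=True)


def call_dml(
    results: pd.DataFrame,
    delta: float = 0.25,
    p_threshold: float = 0.05,
    posthoc_diff_filter: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Flag DMLs: posterior P(|difference| > delta) >= 1 - p_threshold.

    With the difference distributed Normal(diff, se^2), the tail mass is
    ``Phi((diff - delta)/se) + Phi((-diff - delta)/se)``. ``delta = 0.25``
    and ``p_threshold = 0.05`` reproduce a 25%-change call at the 5% level.
    ``posthoc_diff_filter`` instead requires raw significance plus
    ``|diff| >= delta``; ``bh_correct`` additionally gates calls on the
    Benjamini-Hochberg adjusted p.
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError("delta must lie in [0, 1)")
    out = results.copy()
    diff = out["diff"].to_numpy()
    se = out["se_diff"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        post = np.where(
            se > 0,
            stats.norm.cdf((diff - delta) / np.where(se > 0, se, 1))
            + stats.norm.cdf((-diff - delta) / np.where(se > 0, se, 1)),
            np.where(np.abs(diff) > delta, 1.0, np.where(np.abs(diff) < delta, 0.0, 0.5)),
        )
    out["post_prob_gt_delta"] = post
    p_eff = out["p_raw"].to_numpy()
    if bh_correct:
        p_eff = stats.false_discovery_control(p_eff, method="bh")
        out["p_bh"] = p_eff
    if posthoc_diff_filter:
        out["is_dml"] = (p_eff < p_threshold) & (np.abs(diff) >= delta)
    else:
        out["is_dml"] = post >= 1 - p_threshold
        if bh_correct:
            out["is_dml"] &= p_eff < p_threshold
    # direction of change from group 1 to group 2: with group 1 the earlier
    # stage, diff = mu1 - mu2 > 0 means the later group lost methylation
    out["direction"] = np.where(diff > 0, "hypo", np.where(diff < 0, "hyper", "none"))
    return out


def call_dmr(
    flagged: pd.DataFrame,
    delta: float = 0.0,
    p_threshold: float = 0.05,
    min_len: int = 50,
    min_cg: int = 3,
    pct_sig: float = 0.5,
    merge_dist: int = 100,
) -> pd.DataFrame:
    """Aggregate runs of significant same-direction sites into DMRs.

    A site is region-significant when its raw p is below ``p_threshold``
    (with ``delta = 0``, the region caller's default: regions accumulate
    evidence over many sites, so no per-site effect-size gate is imposed)
    or, with ``delta > 0``, when the posterior P(|difference| > delta)
    reaches ``1 - p_threshold``. Seeds are maximal runs of significant
    sites sharing a direction with inter-site gaps <= ``merge_dist``;
    same-direction regions closer than ``merge_dist`` are then merged.
    Each region spans from its first to its last significant site; all
    tested sites of the same context inside the span are members. Filters
    (span >= ``min_len``, members >= ``min_cg``, significant fraction >=
    ``pct_sig``) apply after merging. ``area_stat`` is the summed Wald z
    over member sites. Input must be position-sorted.
    """
    flagged = flagged.copy()
    if delta > 0:
        diff = flagged["diff"].to_numpy()
        se = flagged["se_diff"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            post = np.where(
                se > 0,
                stats.norm.cdf((diff - delta) / np.where(se > 0, se, 1))
                + stats.norm.cdf((-diff - delta) / np.where(se > 0, se, 1)),
                (np.abs(diff) > delta).astype(float),
            )
        flagged["_region_sig"] = post >= 1 - p_threshold
    else:
        flagged["_region_sig"] = flagged["p_raw"] < p_threshold
    flagged["_dir"] = np.where(
        flagged["diff"] > 0, "hypo", np.where(flagged["diff"] < 0, "hyper", "none")
    )
    rows = []
    for (chrom, context), sub in flagged.groupby(["chrom", "context"], sort=True):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError("call_dmr requires input sorted by position with unique sites")
        sig = sub[sub["_region_sig"] & (sub["_dir"] != "none")]
        if sig.empty:
            continue
        spos = sig["pos"].to_numpy()
        sdir = sig["_dir"].to_numpy()
        # seed runs
        runs = []
        start = 0
        for i in range(1, len(sig) + 1):
            if (
                i == len(sig)
                or sdir[i] != sdir[start]
                or spos[i] - spos[i - 1] > merge_dist
            ):
                runs.append((spos[start], spos[i - 1], sdir[start]))
                start = i
        # merge same-direction neighbours closer than merge_dist
        merged = [runs[0]]
        for s, e, d in runs[1:]:
            ps, pe, pdir = merged[-1]
            if d == pdir and s - pe <= merge_dist:
                merged[-1] = (ps, e, d)
            else:
                merged.append((s, e, d))
        for s, e, d in merged:
            span = sub[(sub["pos"] >= s) & (sub["pos"] <= e)]
            n_sites = len(span)
            n_sig = int((span["_region_sig"] & (span["_dir"] == d)).sum())
            length = int(e) - int(s) + 1
            if length < min_len or n_sites < min_cg or n_sig / n_sites < pct_sig:
                continue
            rows.append(
                (
                    chrom,
                    int(s) - 1,  # 0-based half-open over the cytosine span
                    int(e),
                    context,
                    n_sites,
                    n_sig,
                    float(span["diff"].mean()),
                    float(span["wald_z"].sum()),
                    d,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "context",
            "n_sites", "n_sig_sites", "mean_diff", "area_stat", "direction",
        ],
    )


def summarize_dml(results_by_comparison: dict[str, pd.DataFrame]) -> dict:
    """Composition tables over one or more pairwise comparisons.

    Returns hypo/hyper counts by context and per-direction context
    fractions per comparison, per-comparison DML totals, and the fraction
    of distinct DML site keys seen in exactly one comparison.
    """
    if not results_by_comparison:
        raise ValueError("need at least one comparison")
    comp_rows = []
    key_sets = {}
    for name, df in results_by_comparison.items():
        d = df[df["is_dml"]]
        key_sets[name] = set(zip(d["chrom"], d["pos"], d["strand"]))
        for direction in ("hypo", "hyper"):
            sub = d[d["direction"] == direction]
            total = len(sub)
            for ctx in ("CG", "CHG", "CHH"):
                n = int((sub["context"] == ctx).sum())
                comp_rows.append(
                    (name, direction, ctx, n, n / total if total else np.nan)
                )
    composition = pd.DataFrame(
        comp_rows, columns=["comparison", "direction", "context", "n", "fraction"]
    )
    totals = {name: len(s) for name, s in key_sets.items()}
    all_keys: dict = {}
    for s in key_sets.values():
        for kk in s:
            all_keys[kk] = all_keys.get(kk, 0) + 1
    n_distinct = len(all_keys)
    n_unique = sum(1 for v in all_keys.values() if v == 1)
    return {
        "composition": composition,
        "totals": totals,
        "n_distinct_dmls": n_distinct,
        "unique_fraction": (n_unique / n_distinct) if n_distinct else np.nan,
    }
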