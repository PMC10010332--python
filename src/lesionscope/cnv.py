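"""Tumor/normal log-R-ratio (LRR) copy-number pipeline.

The pipeline estimates a copy-number signal from tumor and normal read
depths at population SNP positions, in four steps:

1. **Site selection** — keep SNP positions that are clearly homozygous
   (normal VAF <= 0.05 or >= 0.95) or clearly heterozygous (normal VAF in
   [0.4, 0.6]) in the matched normal, dropping ambiguous sites.
2. **GC adjustment** — within each sample independently, rescale each
   site's depth by (global median depth / median depth of its GC bin),
   removing GC-content capture/coverage bias.  The GC fraction is computed
   over a window centred on the position (101 bp by default: 50 bp of
   flank on each side).
3. **Per-site LRR** — ``LRR_i = log2((t_i/T) / (n_i/N))`` where ``t_i``
   and ``n_i`` are GC-adjusted tumor and normal depths and ``T``, ``N``
   their sums over all evaluated sites (library-size normalisation;
   a median-of-depths normaliser is available as an option).
4. **Representative LRR** — the median of a 1-Mb moving window centred at
   each site, computed within chromosomes only, reported only where the
   window holds enough sites.

Tumor purity and ploidy are not modelled; on a pure diploid tumor a
single-copy loss sits near ``log2(1/2)`` and a single-copy gain near
``log2(3/2)`` (up to the global renormalisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Zygosity",
    "select_snp_sites",
    "gc_adjust_depths",
    "compute_lrr",
    "windowed_lrr",
    "lrr_pipeline",
    "gc_fraction_from_fasta",
]


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    EXCLUDED = "excluded"


SITE_COLUMNS = ["chrom", "pos", "normal_vaf", "normal_depth", "tumor_depth", "gc_fraction"]


def _validate_sites(sites: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if (sites["normal_depth"] < 0).any() or (sites["tumor_depth"] < 0).any():
        raise ValueError("negative depths")
    gc = sites["gc_fraction"]
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc_fraction outside [0, 1]")


def select_snp_sites(
    sites: pd.DataFrame,
    hom_low: float = 0.05,
    hom_high: float = 0.95,
    het_low: float = 0.4,
    het_high: float = 0.6,
) -> pd.DataFrame:
    """Classify sites by normal-sample zygosity and keep informative ones.

    A site is homozygous iff ``vaf <= hom_low`` or ``vaf >= hom_high``,
    heterozygous iff ``het_low <= vaf <= het_high``, otherwise excluded.
    Returns a copy with a ``zygosity`` column, restricted to non-excluded
    sites.
    """
    _validate_sites(sites)
    vaf = sites["normal_vaf"].to_numpy(float)
    if np.isnan(vaf).any():
        raise ValueError("normal_vaf missing at some sites")
    zyg = np.full(len(sites), Zygosity.EXCLUDED.value, dtype=object)
    zyg[(vaf <= hom_low) | (vaf >= hom_high)] = Zygosity.HOMOZYGOUS.value
    zyg[(vaf >= het_low) & (vaf <= het_high)] = Zygosity.HETEROZYGOUS.value
    out = sites.copy()
    out["zygosity"] = zyg
    return out[out["zygosity"] != Zygosity.EXCLUDED.value].reset_index(drop=True)


def _gc_adjust_one(depth: np.ndarray, gc_bin: np.ndarray) -> np.ndarray:
    """Median-scale one sample's depths within GC bins."""
    global_median = np.median(depth)
    if global_median == 0:
        raise ValueError("all-zero depths; cannot GC-adjust")
    adj = np.empty_like(depth, dtype=float)
    for b in np.unique(gc_bin):
        mask = gc_bin == b
        bin_median = np.median(depth[mask])
        if bin_median == 0:
            adj[mask] = 0.0  # flagged downstream: zero-adjusted sites dropped
        else:
            adj[mask] = depth[mask] * (global_median / bin_median)
    return adj


def gc_adjust_depths(sites: pd.DataFrame, bin_width: float = 0.01) -> pd.DataFrame:
    """GC-correct normal and tumor depths by in-bin median scaling.

    Each sample is adjusted independently: sites are binned by GC fraction
    (``bin_width`` resolution) and each depth is multiplied by
    global-median / bin-median.  Returns a copy with ``n_adj`` and
    ``t_adj`` columns.
    """
    _validate_sites(sites)
    if len(sites) == 0:
        out = sites.copy()
        out["n_adj"] = np.array([], dtype=float)
        out["t_adj"] = np.array([], dtype=float)
        return out
    gc_bin = np.floor(
        sites["gc_fraction"].to_numpy(float) / bin_width + 1e-9
    ).astype(int)
    out = sites.copy()
    out["n_adj"] = _gc_adjust_one(sites["normal_depth"].to_numpy(float), gc_bin)
    out["t_adj"] = _gc_adjust_one(sites["tumor_depth"].to_numpy(float), gc_bin)
    return out


def compute_lrr(
    adjusted: pd.DataFrame, normalizer: str = "sum"
) -> pd.DataFrame:
    """Per-site LRR from GC-adjusted depths.

    ``LRR_i = log2((t_i/T) / (n_i/N))`` with ``T`` and ``N`` the sums
    (``normalizer="sum"``) or medians (``normalizer="median"``) of the
    adjusted tumor and normal depths over evaluated sites.  Sites with a
    zero adjusted depth in either sample are dropped (their count is in
    the ``attrs['n_dropped_zero_depth']`` of the result), so the output
    is never infinite.  Invariant to rescaling either sample's depths by
    a constant.
    """
    if normalizer not in ("sum", "median"):
        raise ValueError("normalizer must be 'sum' or 'median'")
    n = adjusted["n_adj"].to_numpy(float)
    t = adjusted["t_adj"].to_numpy(float)
    ok = (n > 0) & (t > 0)
    kept = adjusted[ok].reset_index(drop=True)
    n, t = n[ok], t[ok]
    if len(kept) == 0:
        raise ValueError("no sites with positive adjusted depths")
    agg = np.sum if normalizer == "sum" else np.median
    T, N = agg(t), agg(n)
    out = kept.copy()
    out["lrr"] = np.log2((t / T) / (n / N))
    out.attrs["n_dropped_zero_depth"] = int((~ok).sum())
    return out


def windowed_lrr(
    track: pd.DataFrame,
    window_bp: int = 1_000_000,
    min_sites_per_window: int = 10,
) -> pd.DataFrame:
    """Representative LRR: moving-window median centred at each site.

    For site *i* the representative LRR is the median of ``lrr`` over
    sites *j* on the same chromosome with ``|pos_j - pos_i| <=
    window_bp/2`` (window closed on both ends; even-count median is the
    mean of the two central values).  NaN where fewer than
    ``min_sites_per_window`` sites fall in the window.  Positions must be
    sorted within each chromosome.
    """
    half = window_bp / 2
    rep = np.full(len(track), np.nan)
    offset = 0
    for _, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(float)
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted within chromosome")
        lrr = grp["lrr"].to_numpy(float)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for k in range(len(pos)):
            if hi[k] - lo[k] >= min_sites_per_window:
                rep[offset + k] = np.median(lrr[lo[k]:hi[k]])
        offset += len(pos)
    out = track.copy()
    out["lrr_windowed"] = rep
    return out


def lrr_pipeline(
    sites: pd.DataFrame,
    hom_low: float = 0.05,
    hom_high: float = 0.95,
    het_low: float = 0.4,
    het_high: float = 0.6,
    gc_bin_width: float = 0.01,
    normalizer: str = "sum",
    window_bp: int = 1_000_000,
    min_sites_per_window: int = 10,
) -> pd.DataFrame:
    """End-to-end LRR track: select -> GC-adjust -> LRR -> windowed median.

    ``sites`` must be sorted by (chrom, pos).  Returns the per-site track
    with ``zygosity``, ``n_adj``, ``t_adj``, ``lrr`` and ``lrr_windowed``.
    """
    selected = select_snp_sites(sites, hom_low, hom_high, het_low, het_high)
    adjusted = gc_adjust_depths(selected, bin_width=gc_bin_width)
    track = compute_lrr(adjusted, normalizer=normalizer)
    return windowed_lrr(track, window_bp=window_bp,
                        min_sites_per_window=min_sites_per_window)


def gc_fraction_from_fasta(
    fasta_path: str, chrom: str, pos: int, flank: int = 50
) -> float:
    """GC fraction of the window [pos-flank, pos+flank] (1-based, clipped
    to sequence bounds) from an indexed FASTA."""
    import pysam

    with pysam.FastaFile(fasta_path) as fa:
        length = fa.get_reference_length(chrom)
        start = max(0, pos - 1 - flank)
        end = min(length, pos + flank)
        seq = fa.fetch(chrom, start, end).upper()
    if not seq:
        raise ValueError(f"empty window at {chrom}:{pos}")
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError(f"no called bases in window at {chrom}:{pos}")
    return gc / acgt
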