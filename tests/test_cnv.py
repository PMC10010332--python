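"""LRR copy-number pipeline: site selection, GC adjustment, windowed medians."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lesionscope.cnv import (
    Zygosity,
    compute_lrr,
    gc_adjust_depths,
    lrr_pipeline,
    select_snp_sites,
    windowed_lrr,
)
from lesionscope.simulate import SimConfig, sim_depth_tracks


def site_frame(vafs, normal=100, tumor=100, gc=0.45, chrom="chr1"):
    n = len(vafs)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * 1000,
            "normal_vaf": vafs,
            "normal_depth": normal if np.iterable(normal) else [normal] * n,
            "tumor_depth": tumor if np.iterable(tumor) else [tumor] * n,
            "gc_fraction": gc if np.iterable(gc) else [gc] * n,
        }
    )


@pytest.mark.parametrize(
    "vaf,expected",
    [
        (0.50, Zygosity.HETEROZYGOUS),
        (0.40, Zygosity.HETEROZYGOUS),
        (0.60, Zygosity.HETEROZYGOUS),
        (0.97, Zygosity.HOMOZYGOUS),
        (0.05, Zygosity.HOMOZYGOUS),
        (0.02, Zygosity.HOMOZYGOUS),
    ],
)
def test_zygosity_assignment(vaf, expected):
    out = select_snp_sites(site_frame([vaf]))
    assert out["zygosity"].iloc[0] == expected.value


@pytest.mark.parametrize("vaf", [0.20, 0.061, 0.39, 0.7])
def test_ambiguous_vaf_excluded(vaf):
    assert len(select_snp_sites(site_frame([vaf]))) == 0


def test_gc_adjust_single_bin_is_identity():
    sites = site_frame([0.5] * 5, normal=[80, 90, 100, 110, 120])
    adj = gc_adjust_depths(sites)
    np.testing.assert_allclose(adj["n_adj"], sites["normal_depth"])


def test_gc_adjust_two_bin_example():
    # bin medians 100 and 50, global median 75: depth-50 site -> 75
    sites = site_frame(
        [0.5] * 4,
        normal=[100, 100, 50, 50],
        gc=[0.30, 0.30, 0.60, 0.60],
    )
    adj = gc_adjust_depths(sites)
    np.testing.assert_allclose(adj["n_adj"], [75.0, 75.0, 75.0, 75.0])


def test_gc_adjust_removes_planted_linear_bias(rng):
    gc = rng.uniform(0.3, 0.6, size=4000)
    depth = rng.poisson(100 * (1 + 2.0 * (gc - 0.45)))
    sites = site_frame([0.5] * 4000, normal=depth, tumor=depth, gc=gc)
    adj = gc_adjust_depths(sites)
    rho_before = spearmanr(gc, depth).statistic
    rho_after = spearmanr(gc, adj["n_adj"]).statistic
    assert abs(rho_before) > 0.5
    assert abs(rho_after) < 0.1


def test_gc_adjust_all_zero_depth_errors():
    sites = site_frame([0.5] * 3, normal=[0, 0, 0])
    with pytest.raises(ValueError):
        gc_adjust_depths(sites)


def _with_adj(sites):
    out = sites.copy()
    out["n_adj"] = out["normal_depth"].astype(float)
    out["t_adj"] = out["tumor_depth"].astype(float)
    return out


def test_lrr_zero_when_tumor_equals_normal():
    sites = _with_adj(site_frame([0.5] * 20, normal=100, tumor=100))
    track = compute_lrr(sites)
    np.testing.assert_allclose(track["lrr"], 0.0, atol=1e-12)


def test_lrr_closed_form_for_doubled_half():
    # uniform normal; tumor doubled on half the sites: T/N = 1.5
    n = 200
    tumor = [200] * (n // 2) + [100] * (n // 2)
    sites = _with_adj(site_frame([0.5] * n, normal=100, tumor=tumor))
    track = compute_lrr(sites)
    np.testing.assert_allclose(
        track["lrr"][: n // 2], np.log2(2 / 1.5), atol=1e-12
    )
    np.testing.assert_allclose(
        track["lrr"][n // 2:], np.log2(1 / 1.5), atol=1e-12
    )


def test_lrr_invariant_to_tumor_scaling():
    rng = np.random.default_rng(5)
    tumor = rng.poisson(100, size=50)
    sites = _with_adj(site_frame([0.5] * 50, normal=100, tumor=tumor))
    scaled = sites.copy()
    scaled["t_adj"] = scaled["t_adj"] * 10
    np.testing.assert_allclose(
        compute_lrr(sites)["lrr"], compute_lrr(scaled)["lrr"], atol=1e-12
    )


def test_lrr_drops_zero_depth_sites_without_infinities():
    sites = _with_adj(site_frame([0.5] * 5, normal=[100, 0, 100, 100, 100]))
    track = compute_lrr(sites)
    assert len(track) == 4
    assert track.attrs["n_dropped_zero_depth"] == 1
    assert np.isfinite(track["lrr"]).all()


def test_windowed_constant_track():
    track = site_frame([0.5] * 30)
    track["lrr"] = 0.7
    out = windowed_lrr(track, window_bp=10_000, min_sites_per_window=5)
    interior = out["lrr_windowed"].dropna()
    assert len(interior) > 0
    np.testing.assert_allclose(interior, 0.7)


def test_windowed_median_is_outlier_robust_and_even_count_convention():
    # {-1,-1,-1,5} in one window: median = mean of two central = -1
    track = site_frame([0.5] * 4)
    track["lrr"] = [-1.0, -1.0, -1.0, 5.0]
    out = windowed_lrr(track, window_bp=10_000, min_sites_per_window=4)
    np.testing.assert_allclose(out["lrr_windowed"], -1.0)
    # even-count median: mean of the two central values
    track["lrr"] = [1.0, 2.0, 4.0, 8.0]
    out = windowed_lrr(track, window_bp=10_000, min_sites_per_window=4)
    np.testing.assert_allclose(out["lrr_windowed"], 3.0)


def test_windowed_underpopulated_is_missing():
    track = site_frame([0.5] * 3)
    track["lrr"] = 0.0
    out = windowed_lrr(track, window_bp=10_000, min_sites_per_window=10)
    assert out["lrr_windowed"].isna().all()


def test_windows_do_not_span_chromosomes():
    t1 = site_frame([0.5] * 10, chrom="chr1")
    t2 = site_frame([0.5] * 10, chrom="chr2")
    t1["lrr"], t2["lrr"] = -1.0, 1.0
    track = pd.concat([t1, t2], ignore_index=True)
    out = windowed_lrr(track, window_bp=10**9, min_sites_per_window=5)
    np.testing.assert_allclose(out["lrr_windowed"][:10], -1.0)
    np.testing.assert_allclose(out["lrr_windowed"][10:], 1.0)


def test_windowed_unsorted_positions_rejected():
    track = site_frame([0.5] * 3)
    track.loc[0, "pos"] = 10**7
    track["lrr"] = 0.0
    with pytest.raises(ValueError):
        windowed_lrr(track)


def test_null_track_windowed_mean_near_zero():
    """Tumor generated by the same process as normal -> mean LRR ~ 0."""
    sites, _ = sim_depth_tracks(SimConfig(seed=21, cnv_segments=[]))
    track = lrr_pipeline(sites)
    assert len(track) >= 5000
    assert abs(np.nanmean(track["lrr_windowed"])) < 0.05


def test_planted_deletion_recovered():
    cfg = SimConfig(seed=22)
    sites, segments = sim_depth_tracks(cfg)
    track = lrr_pipeline(sites)
    seg = segments.iloc[0]  # chr1 CN=1 deletion
    interior = track[
        (track["chrom"] == seg["chrom"])
        & (track["pos"] >= seg["start"] + 500_000)
        & (track["pos"] <= seg["end"] - 500_000)
    ]
    expected_ratio = sites["true_copy_number"].mean() / 2
    expected = np.log2((seg["copy_number"] / 2) / expected_ratio)
    assert abs(np.median(interior["lrr_windowed"]) - expected) < 0.15
    assert (interior["lrr_windowed"] < 0).mean() >= 0.99
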