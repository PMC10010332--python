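"""Seeded generators for every input the pipeline consumes.

Each generator emulates the structure of the corresponding study data —
paired lesions sharing trunk mutations with lesion-private branches,
GC-biased tumor/normal depth tracks with planted copy-number segments,
power-law TCR repertoires with planted dominance and exhaustion
structure, and patient cohorts whose lesion trajectories encode known
response groups linked to exponential survival — and returns, next to
the observable tables, a machine-readable truth table for
parameter-recovery and bookkeeping tests.  All randomness flows through
one ``numpy`` generator seeded from ``SimConfig.seed``, so a fixed seed
reproduces every table exactly.

The default configuration is the set of study conditions the package is
exercised under; see the methods note for the rationale behind each
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .neoantigens import AA_ALPHABET, MutationKey, pseudo_rank
from .variants import Consequence, VariantCall

__all__ = [
    "SimConfig",
    "sim_lesion_pair_mutations",
    "sim_depth_tracks",
    "sim_clonotype_tables",
    "sim_cohort",
    "sim_neoantigen_inputs",
    "DEFAULT_COHORT_COMPOSITION",
]

#: Per-cancer-type (nonmixed responders, mixed responders, nonmixed
#: nonresponders): a 503-patient cohort with 70 mixed responders whose
#: per-type mixed-response frequencies round to 18.6% (melanoma), 16.3%
#: (head and neck), 11.5% (NSCLC) and 9.2% (gastric); 13.9% pooled.
DEFAULT_COHORT_COMPOSITION = {
    "melanoma": (50, 27, 68),
    "head_and_neck": (15, 14, 57),
    "NSCLC": (35, 20, 119),
    "gastric": (14, 9, 75),
}


@dataclass
class SimConfig:
    """Study conditions for all generators.  ``seed`` fixes every draw."""

    seed: int = 0

    # paired-lesion mutations
    n_trunk_mutations: int = 60
    n_private_a: int = 30
    n_private_b: int = 20
    depth_mean: float = 100.0
    decoys_per_criterion: int = 10
    nonsynonymous_fraction: float = 0.75

    # depth tracks / copy number
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 30_000_000}
    )
    site_spacing: int = 5_000
    gc_bias_slope: float = 1.5  # relative depth change per unit GC deviation
    cnv_segments: list = field(
        default_factory=lambda: [
            ("chr1", 20_000_000, 22_000_000, 1),
            ("chr2", 10_000_000, 13_000_000, 3),
        ]
    )

    # TCR repertoire
    n_clonotypes: int = 200
    n_cells_per_sample: int = 8_000
    clone_freq_alpha: float = 1.2  # power-law exponent of clone sizes
    dominance_proportions: tuple = (0.15, 0.65, 0.20)  # A-dom, equiv, B-dom
    dominance_ratio: float = 4.0  # planted frequency ratio for dominant clones
    dominant_mass_fraction: float = 0.2  # repertoire share of a sample's own dominant clones
    exhausted_enrichment_or: float = 4.0
    exhausted_base_prob: float = 0.10  # P(exhausted) for B-dominant clones
    ambiguous_rate: float = 0.05
    no_trb_rate: float = 0.08
    qc_fail_rate: float = 0.05

    # cohort / survival
    cohort_composition: dict = field(
        default_factory=lambda: dict(DEFAULT_COHORT_COMPOSITION)
    )
    n_local_therapy_mixed: int = 13
    pfs_scale_days: dict = field(
        default_factory=lambda: {
            "nonmixed_responder": 500.0,
            "mixed_responder": 250.0,
            "nonmixed_nonresponder": 120.0,
        }
    )
    os_scale_factor: float = 2.2  # OS scale = factor x PFS scale
    censor_scale_days: float = 1_500.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        segs = sorted(self.cnv_segments)
        for (c1, s1, e1, cn1), (c2, s2, e2, cn2) in zip(segs, segs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("cnv_segments overlap")
        for _, _, _, cn in self.cnv_segments:
            if cn not in (0, 1, 2, 3, 4):
                raise ValueError("copy_number must be in {0,1,2,3,4}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# paired-lesion somatic mutations


def _clean_call(
    rng: np.random.Generator, chrom: str, pos: int, config: SimConfig,
    nonsyn: bool,
) -> VariantCall:
    """A call that passes every exclusion criterion with margin."""
    depth = max(int(rng.poisson(config.depth_mean)), 25)
    vaf = rng.uniform(0.12, 0.5)
    alt = int(np.clip(rng.binomial(depth, vaf), 4, depth - 2))
    alt_fwd = int(np.clip(rng.binomial(alt, 0.5), 1, alt - 1))
    ref = depth - alt
    ref_fwd = int(rng.binomial(ref, 0.5))
    bases = ["A", "C", "G", "T"]
    r, a = rng.choice(4, size=2, replace=False)
    return VariantCall(
        chrom=chrom, pos=pos, ref=bases[r], alt=bases[a],
        tumor_alt_fwd=alt_fwd, tumor_alt_rev=alt - alt_fwd,
        tumor_ref_fwd=ref_fwd, tumor_ref_rev=ref - ref_fwd,
        normal_alt=int(rng.integers(0, 2)),
        normal_total=max(int(rng.poisson(config.depth_mean)), 20),
        in_population_db=False,
        consequence=Consequence.NONSYNONYMOUS if nonsyn else Consequence.SYNONYMOUS,
    )


def _decoy_call(
    rng: np.random.Generator, chrom: str, pos: int, config: SimConfig,
    criterion: str,
) -> VariantCall:
    """A call engineered to fail exactly one exclusion criterion."""
    call = _clean_call(rng, chrom, pos, config, nonsyn=bool(rng.random() < 0.5))
    if criterion == "total_reads":
        # shrink to depth in [4, 19] keeping both strands and VAF >= 0.05
        depth = int(rng.integers(8, 20))
        alt = max(4, int(round(depth * 0.3)))
        return VariantCall(
            chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
            tumor_alt_fwd=alt // 2 if alt // 2 >= 1 else 1,
            tumor_alt_rev=alt - max(alt // 2, 1),
            tumor_ref_fwd=(depth - alt) // 2,
            tumor_ref_rev=depth - alt - (depth - alt) // 2,
            normal_alt=0, normal_total=call.normal_total,
            consequence=call.consequence,
        )
    if criterion == "low_vaf":
        depth = max(int(rng.poisson(config.depth_mean)), 60)
        alt = 2  # VAF well below 0.05 at depth >= 60
        return VariantCall(
            chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
            tumor_alt_fwd=1, tumor_alt_rev=1,
            tumor_ref_fwd=(depth - alt) // 2,
            tumor_ref_rev=depth - alt - (depth - alt) // 2,
            normal_alt=0, normal_total=call.normal_total,
            consequence=call.consequence,
        )
    if criterion == "germline_alt":
        return VariantCall(
            chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
            tumor_alt_fwd=call.tumor_alt_fwd, tumor_alt_rev=call.tumor_alt_rev,
            tumor_ref_fwd=call.tumor_ref_fwd, tumor_ref_rev=call.tumor_ref_rev,
            normal_alt=int(rng.integers(3, 8)),
            normal_total=max(call.normal_total, 10),
            consequence=call.consequence,
        )
    if criterion == "single_strand":
        alt = call.tumor_alt
        return VariantCall(
            chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
            tumor_alt_fwd=alt, tumor_alt_rev=0,
            tumor_ref_fwd=call.tumor_ref_fwd, tumor_ref_rev=call.tumor_ref_rev,
            normal_alt=call.normal_alt, normal_total=call.normal_total,
            consequence=call.consequence,
        )
    if criterion == "population_db":
        return VariantCall(
            chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
            tumor_alt_fwd=call.tumor_alt_fwd, tumor_alt_rev=call.tumor_alt_rev,
            tumor_ref_fwd=call.tumor_ref_fwd, tumor_ref_rev=call.tumor_ref_rev,
            normal_alt=call.normal_alt, normal_total=call.normal_total,
            in_population_db=True,
            consequence=call.consequence,
        )
    raise ValueError(f"unknown criterion {criterion!r}")


def sim_lesion_pair_mutations(config: SimConfig):
    """Two lesions' candidate variant sets with known trunk/branch truth.

    Trunk mutations appear in both lesions (independently re-sampled read
    counts), private mutations in one.  ``decoys_per_criterion`` extra
    calls per lesion are planted to fail exactly one exclusion criterion
    each.  Returns ``(calls_a, calls_b, truth)`` where ``truth`` is a
    DataFrame with one row per planted variant (category, lesions,
    consequence, expected retention).
    """
    rng = config.rng()
    pos_iter = iter(range(1_000_000, 200_000_000, 1_001))
    truth_rows = []
    calls_a: list[VariantCall] = []
    calls_b: list[VariantCall] = []

    def plant(category: str, lesions: Sequence[str]) -> None:
        pos = next(pos_iter)
        nonsyn = bool(rng.random() < config.nonsynonymous_fraction)
        ref_alt = None
        for lesion in lesions:
            call = _clean_call(rng, "chr1", pos, config, nonsyn)
            if ref_alt is None:
                ref_alt = (call.ref, call.alt)
            else:  # trunk mutation: identical allele in both lesions
                call = VariantCall(
                    **{**call.__dict__, "ref": ref_alt[0], "alt": ref_alt[1]}
                )
            (calls_a if lesion == "A" else calls_b).append(call)
        truth_rows.append(
            {
                "chrom": "chr1", "pos": pos,
                "ref": ref_alt[0], "alt": ref_alt[1],
                "category": category, "lesions": "".join(lesions),
                "nonsynonymous": nonsyn, "expected_retained": True,
            }
        )

    for _ in range(config.n_trunk_mutations):
        plant("trunk", ("A", "B"))
    for _ in range(config.n_private_a):
        plant("private_A", ("A",))
    for _ in range(config.n_private_b):
        plant("private_B", ("B",))

    from .variants import CRITERION_LABELS

    for criterion in CRITERION_LABELS:
        for _ in range(config.decoys_per_criterion):
            for lesion, bucket in (("A", calls_a), ("B", calls_b)):
                pos = next(pos_iter)
                call = _decoy_call(rng, "chr1", pos, config, criterion)
                bucket.append(call)
                truth_rows.append(
                    {
                        "chrom": "chr1", "pos": pos,
                        "ref": call.ref, "alt": call.alt,
                        "category": f"decoy_{criterion}", "lesions": lesion,
                        "nonsynonymous": call.consequence
                        == Consequence.NONSYNONYMOUS,
                        "expected_retained": False,
                    }
                )
    return calls_a, calls_b, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# depth tracks with planted copy-number segments


def sim_depth_tracks(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP-site depth table with GC bias and planted CNV segments.

    Sites are placed every ``site_spacing`` bp.  Normal depth is Poisson
    with a GC-dependent mean (``1 + gc_bias_slope * (gc - 0.45)``, floored
    at 0.1); tumor depth additionally scales by ``copy_number / 2``
    inside planted segments.  Normal VAFs are drawn binomially from true
    genotypes (hom-ref, het, hom-alt, plus a minority of noisy
    intermediate sites that the zygosity selection should exclude).
    Returns ``(sites, segments)``; ``segments`` carries the planted truth.
    """
    rng = config.rng()
    seg_df = pd.DataFrame(
        config.cnv_segments, columns=["chrom", "start", "end", "copy_number"]
    )
    frames = []
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(config.site_spacing, length + 1, config.site_spacing)
        n = pos.size
        gc = np.clip(rng.normal(0.45, 0.07, size=n), 0.25, 0.7)
        gc_effect = np.maximum(1.0 + config.gc_bias_slope * (gc - 0.45), 0.1)
        normal_depth = rng.poisson(config.depth_mean * gc_effect)
        cn = np.full(n, 2.0)
        for _, seg in seg_df[seg_df["chrom"] == chrom].iterrows():
            inside = (pos >= seg["start"]) & (pos <= seg["end"])
            cn[inside] = seg["copy_number"]
        tumor_depth = rng.poisson(config.depth_mean * gc_effect * cn / 2.0)
        geno = rng.choice(4, size=n, p=[0.35, 0.30, 0.25, 0.10])
        p_alt = np.array([0.005, 0.5, 0.995, 0.22])[geno]
        alt = rng.binomial(np.maximum(normal_depth, 1), p_alt)
        vaf = np.where(normal_depth > 0, alt / np.maximum(normal_depth, 1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "normal_vaf": vaf,
                    "normal_depth": normal_depth,
                    "tumor_depth": tumor_depth,
                    "gc_fraction": gc,
                    "true_copy_number": cn,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    return sites, seg_df


# ---------------------------------------------------------------------------
# single-cell TCR repertoires


def _power_law_freqs(rng, n: int, alpha: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-alpha)
    w = rng.permutation(w)
    return w / w.sum()


def sim_clonotype_tables(config: SimConfig):
    """Contig annotations + cell metadata for two lesions, with truth.

    Clonotype base frequencies follow a truncated power law; each
    clonotype carries a planted dominance class (sample-A frequency
    ``dominance_ratio`` times sample B's, or vice versa, or equal) and an
    exhausted flag drawn so the planted flags achieve
    ``exhausted_enrichment_or`` in expectation between A- and B-dominant
    clones.  Cells of exhausted clonotypes sit mostly in the exhausted
    cluster.  Ambiguous (competing second β), β-less and QC-fail cells
    are planted at the configured rates and recorded per cell.

    Returns ``(contigs, cells, clone_truth, cell_truth)`` DataFrames:
    ``contigs`` in the 10x filtered-contig dialect and ``cells`` in the
    metadata dialect the readers accept.
    """
    rng = config.rng()
    n = config.n_clonotypes
    base = _power_law_freqs(rng, n, config.clone_freq_alpha)
    p_a, p_eq, p_b = config.dominance_proportions
    dom = rng.choice(
        ["A_dominant", "equivalent", "B_dominant"], size=n, p=[p_a, p_eq, p_b]
    )
    r = config.dominance_ratio
    # Build the two frequency vectors so the planted per-clone ratio
    # (r : 1 for A-dominant, 1 : r for B-dominant, 1 : 1 for equivalent)
    # holds exactly AFTER each sample is normalised to sum 1.  Applying
    # the ratio before normalisation would let the two samples' total
    # masses diverge and silently re-label planted classes.  Both sums
    # equal 1 only when the A-dominant mass in sample B is 1/r times the
    # B-dominant mass, so the dominant-class masses are pinned and the
    # equivalent clones absorb the remainder.
    is_a, is_b = dom == "A_dominant", dom == "B_dominant"
    is_e = ~(is_a | is_b)
    if is_a.any() and is_b.any():
        m_dom = config.dominant_mass_fraction
        m_b, m_a = m_dom, m_dom / r
        m_e = 1.0 - m_a - m_b
        freq_b = np.where(
            is_a, base * (m_a / base[is_a].sum()),
            np.where(is_b, base * (m_b / base[is_b].sum()),
                     base * (m_e / base[is_e].sum())),
        )
        freq_a = freq_b * np.where(is_a, r, np.where(is_b, 1.0 / r, 1.0))
    else:
        # degenerate configurations (a single dominant class) cannot hold
        # exact ratios in both normalised samples; fall back to pre-
        # normalisation weighting
        w_a = base * np.where(is_a, r, 1.0)
        w_b = base * np.where(is_b, r, 1.0)
        freq_a, freq_b = w_a / w_a.sum(), w_b / w_b.sum()

    odds_b = config.exhausted_base_prob / (1 - config.exhausted_base_prob)
    odds_a = odds_b * config.exhausted_enrichment_or
    p_ex = np.where(
        dom == "A_dominant",
        odds_a / (1 + odds_a),
        config.exhausted_base_prob,
    )
    exhausted = rng.random(n) < p_ex

    v_genes = [f"TRBV{i}" for i in rng.integers(1, 30, size=n)]
    j_genes = [f"TRBJ{i}-{j}" for i, j in zip(rng.integers(1, 3, size=n),
                                              rng.integers(1, 7, size=n))]
    nts = np.array(list("ACGT"))
    cdr3s = ["TGT" + "".join(rng.choice(nts, size=36)) + "TTT" for _ in range(n)]
    if len(set(cdr3s)) != n:  # astronomically unlikely; regenerate clashes
        seen = set()
        for i, c in enumerate(cdr3s):
            while c in seen:
                c = "TGT" + "".join(rng.choice(nts, size=36)) + "TTT"
            seen.add(c)
            cdr3s[i] = c

    clone_truth = pd.DataFrame(
        {
            "trb_v": v_genes, "trb_j": j_genes, "cdr3_nt": cdr3s,
            "freq_A": freq_a, "freq_B": freq_b,
            "planted_dominance": dom, "planted_exhausted": exhausted,
        }
    )

    clusters = [
        "exhausted_cd8", "naive_cd4", "naive_cd8", "regulatory_t",
        "cytotoxic_cd4", "follicular_helper_cd4", "activated_memory_cd4",
        "activated_cd8", "memory_cd8",
    ]
    contig_rows, cell_rows, cell_truth_rows = [], [], []
    for sample, freqs in (("A", freq_a), ("B", freq_b)):
        clone_idx = rng.choice(n, size=config.n_cells_per_sample, p=freqs)
        for i, ci in enumerate(clone_idx):
            barcode = f"{sample}-{i:05d}"
            u = rng.random()
            if u < config.qc_fail_rate:
                planted = "qc_fail"
            elif u < config.qc_fail_rate + config.no_trb_rate:
                planted = "no_trb"
            elif u < config.qc_fail_rate + config.no_trb_rate + config.ambiguous_rate:
                planted = "ambiguous"
            else:
                planted = "ok"

            if planted == "qc_fail":
                which = rng.integers(0, 3)
                mito = 0.25 if which == 0 else rng.uniform(0.0, 0.08)
                genes = 150 if which == 1 else (4500 if which == 2 else
                                                int(rng.integers(400, 3000)))
            else:
                mito = rng.uniform(0.0, 0.08)
                genes = int(rng.integers(400, 3000))

            if exhausted[ci]:
                cluster = "exhausted_cd8" if rng.random() < 0.9 else str(
                    rng.choice(clusters[1:])
                )
            else:
                cluster = "exhausted_cd8" if rng.random() < 0.05 else str(
                    rng.choice(clusters[1:])
                )

            top_umis = 2 + int(rng.poisson(4))
            if planted != "no_trb":
                contig_rows.append(
                    {
                        "barcode": barcode, "chain": "TRB",
                        "v_gene": v_genes[ci], "j_gene": j_genes[ci],
                        "cdr3_nt": cdr3s[ci], "cdr3": "", "umis": top_umis,
                    }
                )
                if planted == "ambiguous":
                    # competing beta with > half the top clone's UMIs
                    cj = int(rng.integers(0, n))
                    if cj == ci:
                        cj = (cj + 1) % n
                    contig_rows.append(
                        {
                            "barcode": barcode, "chain": "TRB",
                            "v_gene": v_genes[cj], "j_gene": j_genes[cj],
                            "cdr3_nt": cdr3s[cj], "cdr3": "",
                            "umis": top_umis // 2 + 1,
                        }
                    )
            if rng.random() < 0.8:  # most cells also have an alpha
                contig_rows.append(
                    {
                        "barcode": barcode, "chain": "TRA",
                        "v_gene": f"TRAV{rng.integers(1, 40)}",
                        "j_gene": f"TRAJ{rng.integers(1, 60)}",
                        "cdr3_nt": "TGT" + "".join(rng.choice(nts, size=30)),
                        "cdr3": "", "umis": 1 + int(rng.poisson(2)),
                    }
                )
            cell_rows.append(
                {
                    "barcode": barcode, "sample": sample,
                    "mito_fraction": round(mito, 4), "n_genes": genes,
                    "cluster": cluster,
                }
            )
            cell_truth_rows.append(
                {
                    "barcode": barcode, "sample": sample,
                    "clone_index": ci, "planted_status": planted,
                }
            )
    return (
        pd.DataFrame(contig_rows),
        pd.DataFrame(cell_rows),
        clone_truth,
        pd.DataFrame(cell_truth_rows),
    )


# ---------------------------------------------------------------------------
# patient cohorts with known response groups


def _trajectory(rng, group: str, patient: str) -> list[dict]:
    """Lesion observations implementing one group's template with margins
    well beyond the -30%/+20% classification thresholds."""
    n_lesions = int(rng.integers(2, 5))
    scans = [0.0, 60.0, 120.0]
    rows = []
    for li in range(n_lesions):
        d0 = float(rng.uniform(12, 40))
        if group == "nonmixed_responder":
            changes = (-0.5, -0.6)
        elif group == "nonmixed_nonresponder":
            changes = (0.35, 0.5)
        else:  # mixed: first lesion regresses, the rest progress
            changes = (-0.5, -0.6) if li == 0 else (0.35, 0.5)
        diam = [d0, d0 * (1 + changes[0]), d0 * (1 + changes[1])]
        for t, d in zip(scans, diam):
            rows.append(
                {
                    "patient": patient, "lesion": f"L{li + 1}",
                    "time_days": t, "diameter_mm": round(d, 1),
                    "is_new": False,
                }
            )
    if group == "mixed_responder" and rng.random() < 0.3:
        rows.append(
            {
                "patient": patient, "lesion": f"L{n_lesions + 1}",
                "time_days": 90.0, "diameter_mm": float(rng.uniform(8, 15)),
                "is_new": True,
            }
        )
    return rows


def sim_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort of lesion trajectories and survival outcomes with truth.

    Group membership per cancer type follows ``cohort_composition``
    exactly (deterministic allocation); the first
    ``n_local_therapy_mixed`` mixed responders carry the local-therapy
    flag.  PFS is exponential with the group's scale, OS
    ``os_scale_factor`` times longer, both independently right-censored
    (exponential censoring at ``censor_scale_days``).

    Returns ``(lesions, patients, truth)``.
    """
    rng = config.rng()
    group_names = ("nonmixed_responder", "mixed_responder", "nonmixed_nonresponder")
    lesion_rows, patient_rows, truth_rows = [], [], []
    pid = 0
    n_mixed_seen = 0
    for cancer_type, counts in config.cohort_composition.items():
        for group, n_group in zip(group_names, counts):
            for _ in range(n_group):
                pid += 1
                patient = f"P{pid:04d}"
                lesion_rows.extend(_trajectory(rng, group, patient))
                pfs_scale = config.pfs_scale_days[group]
                pfs_t = rng.exponential(pfs_scale)
                os_t = rng.exponential(pfs_scale * config.os_scale_factor)
                os_t = max(os_t, pfs_t)  # death never precedes progression
                pfs_c = rng.exponential(config.censor_scale_days)
                os_c = rng.exponential(config.censor_scale_days)
                local = False
                if group == "mixed_responder":
                    n_mixed_seen += 1
                    local = n_mixed_seen <= config.n_local_therapy_mixed
                patient_rows.append(
                    {
                        "patient": patient, "cancer_type": cancer_type,
                        "pfs_days": round(min(pfs_t, pfs_c), 1),
                        "pfs_event": int(pfs_t <= pfs_c),
                        "os_days": round(min(os_t, os_c), 1),
                        "os_event": int(os_t <= os_c),
                        "local_therapy": local,
                    }
                )
                truth_rows.append(
                    {
                        "patient": patient, "cancer_type": cancer_type,
                        "planted_group": group, "local_therapy": local,
                    }
                )
    return (
        pd.DataFrame(lesion_rows),
        pd.DataFrame(patient_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# neoantigen inputs (proteins, annotated mutations, binding table)


def sim_neoantigen_inputs(
    config: SimConfig,
    n_strong_shared: int = 4,
    n_strong_private_a: int = 6,
    n_strong_private_b: int = 0,
    alleles: Sequence[str] = ("HLA-A*02:01", "HLA-B*07:02"),
):
    """Trunk/branch mutations with protein context and a binding table.

    Generates random protein sequences, assigns each planted mutation an
    interior residue substitution, and builds a binding table covering
    every mutant 9-mer x allele pair with synthetic weak ranks except for
    a chosen number of planted strong binders per category (shared /
    private-A / private-B; the zero default for private B mirrors a
    lesion contributing no private strong binder).  Returns
    ``(mutations_by_lesion, protein_seqs, binding_table, truth)``.
    """
    from .neoantigens import enumerate_mutant_9mers

    rng = config.rng()
    aa = np.array(sorted(AA_ALPHABET))
    categories = (
        [("shared", True)] * config.n_trunk_mutations
        + [("private_A", True)] * config.n_private_a
        + [("private_B", True)] * config.n_private_b
    )
    strong_quota = {
        "shared": n_strong_shared,
        "private_A": n_strong_private_a,
        "private_B": n_strong_private_b,
    }
    muts_a, muts_b = [], []
    protein_seqs: dict[str, str] = {}
    binding: dict[tuple[str, str], float] = {}
    truth_rows = []
    for i, (category, _) in enumerate(categories):
        prot = f"PROT{i:04d}"
        L = int(rng.integers(60, 200))
        seq = "".join(rng.choice(aa, size=L))
        protein_seqs[prot] = seq
        p = int(rng.integers(10, L - 10))
        ref_aa = seq[p - 1]
        alt_aa = str(rng.choice([x for x in aa if x != ref_aa]))
        m = MutationKey(
            chrom="chr1", pos=1_000 + i * 500, ref="C", alt="T",
            protein_id=prot, protein_pos=p, ref_aa=ref_aa, alt_aa=alt_aa,
        )
        if category in ("shared", "private_A"):
            muts_a.append(m)
        if category in ("shared", "private_B"):
            muts_b.append(m)
        peptides = enumerate_mutant_9mers(seq, p, alt_aa)
        make_strong = strong_quota[category] > 0
        if make_strong:
            strong_quota[category] -= 1
        strong_pep = peptides[int(rng.integers(0, len(peptides)))] if make_strong else None
        for pep in peptides:
            for allele in alleles:
                if pep == strong_pep and allele == alleles[0]:
                    binding[(pep, allele)] = float(rng.uniform(0.05, 0.45))
                else:
                    binding[(pep, allele)] = float(rng.uniform(0.6, 80.0))
        truth_rows.append(
            {
                "protein": prot, "category": category,
                "strong_peptide": strong_pep,
                "strong_allele": alleles[0] if strong_pep else None,
            }
        )
    return (
        {"A": muts_a, "B": muts_b},
        protein_seqs,
        binding,
        pd.DataFrame(truth_rows),
    )
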