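"""Single-cell TCR clonotype QC, diversity, dominance and enrichment.

Per-cell chain evidence (10x-style contig annotations) is resolved to a
clonotype per cell under two rules: cells without a reconstructed TCRβ
chain are dropped (β defines clonotype identity; α-less cells are kept),
and cells whose second-ranked clonotype has more than half the UMIs of
the top one are labelled ambiguous (a tie at the top is also ambiguous).
Cell QC removes likely dying cells, empty droplets and doublets
(mitochondrial fraction > 10%, fewer than 200 or more than 4,000 genes).

On the resolved repertoire the module computes per-sample/per-cluster
Pielou evenness, classifies clonotypes shared between two lesions as
A-dominant / equivalent / B-dominant by a frequency-ratio rule, and
tests whether exhausted clonotypes are enriched among one lesion's
dominant clonotypes with a Fisher exact test.  A rule-based marker
annotator labels expression clusters (e.g. CD8A+PDCD1+HAVCR2 -> exhausted
CD8+ T cells) as an explicit, testable surrogate for manual annotation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .stats import fisher_exact

__all__ = [
    "CellRecord",
    "ChainEvidence",
    "ResolvedCell",
    "DominanceClass",
    "qc_cells",
    "resolve_cell_clonotype",
    "resolve_repertoire",
    "pielou_evenness",
    "clonotype_counts",
    "top_clonotypes",
    "classify_dominance",
    "exhausted_enrichment",
    "annotate_clusters",
    "DEFAULT_MARKER_RULES",
]


@dataclass(frozen=True)
class CellRecord:
    """Per-cell QC metadata with the expression-cluster assignment."""

    barcode: str
    sample: str
    mito_fraction: float
    n_genes: int
    cluster: str = "unassigned"

    def __post_init__(self) -> None:
        if not 0 <= self.mito_fraction <= 1:
            raise ValueError("mito_fraction outside [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass(frozen=True)
class ChainEvidence:
    """One reconstructed TCR chain for a cell, with its UMI support."""

    barcode: str
    chain: str  # "TRA" or "TRB"
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str = ""
    umis: int = 1

    def __post_init__(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise ValueError(f"chain must be TRA or TRB, got {self.chain!r}")
        if self.umis < 1:
            raise ValueError("umis must be >= 1")


#: Clonotype identity: (TRB V gene, TRB J gene, TRB CDR3 nucleotide).
ClonotypeKey = tuple


@dataclass
class ResolvedCell:
    barcode: str
    status: str  # "resolved" | "dropped_no_trb" | "ambiguous"
    clonotype: Optional[ClonotypeKey] = None
    tra: Optional[tuple] = None  # optional paired-alpha annotation


class DominanceClass(str, Enum):
    A_DOMINANT = "A_dominant"
    EQUIVALENT = "equivalent"
    B_DOMINANT = "B_dominant"


def qc_cells(
    cells: Iterable[CellRecord],
    max_mito: float = 0.10,
    min_genes: int = 200,
    max_genes: int = 4000,
) -> list[CellRecord]:
    """Retain cells passing QC; boundary values are retained.

    Exclusions are strict: mitochondrial fraction *above* ``max_mito``,
    *fewer than* ``min_genes`` or *more than* ``max_genes`` detected genes.
    """
    return [
        c
        for c in cells
        if c.mito_fraction <= max_mito and min_genes <= c.n_genes <= max_genes
    ]


def resolve_cell_clonotype(chains: Sequence[ChainEvidence]) -> ResolvedCell:
    """Resolve one cell's chains to a clonotype, or drop/flag the cell.

    No TRB chain -> ``dropped_no_trb``.  With several candidate β
    clonotypes (distinct V/J/CDR3nt, UMIs summed per candidate) the top
    one by UMIs is taken, unless the runner-up has more than half the
    top's UMIs — or exactly ties it — in which case the cell is
    ``ambiguous``.  The top TRA, when present, is attached as annotation.
    """
    if not chains:
        return ResolvedCell(barcode="", status="dropped_no_trb")
    barcode = chains[0].barcode
    if any(ch.barcode != barcode for ch in chains):
        raise ValueError("chains from multiple barcodes passed as one cell")

    trb_umis: dict[ClonotypeKey, int] = defaultdict(int)
    tra_umis: dict[tuple, int] = defaultdict(int)
    for ch in chains:
        key = (ch.v_gene, ch.j_gene, ch.cdr3_nt)
        if ch.chain == "TRB":
            trb_umis[key] += ch.umis
        else:
            tra_umis[key] += ch.umis
    if not trb_umis:
        return ResolvedCell(barcode=barcode, status="dropped_no_trb")

    ranked = sorted(trb_umis.items(), key=lambda kv: (-kv[1], kv[0]))
    top_key, top_n = ranked[0]
    if len(ranked) > 1:
        second_n = ranked[1][1]
        # "more than half" is strict; an exact tie for the top is ambiguous
        if second_n > top_n / 2 or second_n == top_n:
            return ResolvedCell(barcode=barcode, status="ambiguous")
    tra = None
    if tra_umis:
        tra = max(sorted(tra_umis), key=lambda k: tra_umis[k])
    return ResolvedCell(barcode=barcode, status="resolved",
                        clonotype=top_key, tra=tra)


def resolve_repertoire(
    chains: Iterable[ChainEvidence],
    cells: Iterable[CellRecord],
    max_mito: float = 0.10,
    min_genes: int = 200,
    max_genes: int = 4000,
) -> pd.DataFrame:
    """QC + clonotype resolution for a whole sample set.

    Returns one row per input cell (barcode, sample, cluster, status,
    clonotype key columns).  Statuses partition the cells:
    ``qc_filtered``, ``dropped_no_trb``, ``ambiguous``, ``resolved``.
    Chains whose barcode has no metadata row are ignored with a warning.
    """
    cells = list(cells)
    by_barcode: dict[str, list[ChainEvidence]] = defaultdict(list)
    known = {c.barcode for c in cells}
    orphans = set()
    for ch in chains:
        if ch.barcode not in known:
            orphans.add(ch.barcode)
            continue
        by_barcode[ch.barcode].append(ch)
    if orphans:
        warnings.warn(f"{len(orphans)} contig barcodes without cell metadata ignored")

    passed = {c.barcode for c in qc_cells(cells, max_mito, min_genes, max_genes)}
    rows = []
    for cell in cells:
        if cell.barcode not in passed:
            status, key, tra = "qc_filtered", None, None
        else:
            res = resolve_cell_clonotype(by_barcode.get(cell.barcode, []))
            status, key, tra = res.status, res.clonotype, res.tra
        rows.append(
            {
                "barcode": cell.barcode,
                "sample": cell.sample,
                "cluster": cell.cluster,
                "status": status,
                "trb_v": key[0] if key else None,
                "trb_j": key[1] if key else None,
                "cdr3_nt": key[2] if key else None,
            }
        )
    return pd.DataFrame(rows)


def pielou_evenness(counts) -> float:
    """Pielou's evenness J = H' / ln(S) of a clone-size vector.

    H' is the Shannon entropy of clone frequencies and S the number of
    clones with positive counts (zeros are dropped).  J is 1 for a
    perfectly even repertoire and tends to 0 under domination by one
    clone; it is invariant to rescaling the counts.  Requires S >= 2.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0]
    s = counts.size
    if s < 2:
        raise ValueError("evenness needs at least two clones (ln S = 0)")
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(s))


def clonotype_counts(resolved: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, clonotype) cell counts and within-sample frequencies
    from a resolved repertoire table (``status == "resolved"`` rows)."""
    res = resolved[resolved["status"] == "resolved"]
    counts = (
        res.groupby(["sample", "trb_v", "trb_j", "cdr3_nt"], sort=False)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    counts["frequency"] = counts.groupby("sample")["n_cells"].transform(
        lambda x: x / x.sum()
    )
    return counts


def top_clonotypes(counts: pd.DataFrame, sample: str, n: int = 10) -> pd.DataFrame:
    """Top-n clonotypes of a sample by cell count, ties broken
    lexicographically by CDR3 nucleotide sequence for determinism."""
    sub = counts[counts["sample"] == sample]
    return (
        sub.sort_values(["n_cells", "cdr3_nt"], ascending=[False, True])
        .head(n)
        .reset_index(drop=True)
    )


def classify_dominance(
    freq_a: Mapping[ClonotypeKey, float],
    freq_b: Mapping[ClonotypeKey, float],
    cells_a: Mapping[ClonotypeKey, int],
    cells_b: Mapping[ClonotypeKey, int],
    ratio_threshold: float = 2.0,
    min_cells: int = 2,
) -> dict[ClonotypeKey, DominanceClass]:
    """Classify merged clonotypes as A-dominant / equivalent / B-dominant.

    A clonotype is A-dominant when its frequency in sample A is at least
    ``ratio_threshold`` times its frequency in B (a clonotype absent from
    B counts as dominated by A when A holds >= ``min_cells`` of its
    cells); B-dominant symmetrically; otherwise equivalent.  Clonotypes
    not reaching ``min_cells`` cells in either sample are excluded.  The
    classification is antisymmetric under exchanging the samples.
    """
    if ratio_threshold < 1:
        raise ValueError("ratio_threshold must be >= 1")
    out: dict[ClonotypeKey, DominanceClass] = {}
    for key in set(freq_a) | set(freq_b):
        fa, fb = freq_a.get(key, 0.0), freq_b.get(key, 0.0)
        na, nb = cells_a.get(key, 0), cells_b.get(key, 0)
        if max(na, nb) < min_cells:
            continue
        if fa == 0.0 and fb == 0.0:
            continue
        if fb == 0.0:
            out[key] = (
                DominanceClass.A_DOMINANT
                if na >= min_cells
                else DominanceClass.EQUIVALENT
            )
        elif fa == 0.0:
            out[key] = (
                DominanceClass.B_DOMINANT
                if nb >= min_cells
                else DominanceClass.EQUIVALENT
            )
        elif fa >= ratio_threshold * fb:
            out[key] = DominanceClass.A_DOMINANT
        elif fb >= ratio_threshold * fa:
            out[key] = DominanceClass.B_DOMINANT
        else:
            out[key] = DominanceClass.EQUIVALENT
    return out


def exhausted_enrichment(
    dominance: Mapping[ClonotypeKey, DominanceClass],
    exhausted_fraction: Mapping[ClonotypeKey, float],
    exhausted_cell_fraction_threshold: float = 0.5,
) -> dict:
    """Fisher test of exhausted-clonotype enrichment by dominance side.

    Builds the 2x2 table with rows {A-dominant, B-dominant} (equivalent
    clonotypes are excluded) and columns {exhausted, not exhausted},
    where a clonotype is exhausted when more than
    ``exhausted_cell_fraction_threshold`` of its cells sit in the
    exhausted cluster.  Returns counts, the odds ratio and the two-sided
    Fisher p-value (p = 1 with a warning on an empty margin).
    """
    a_ex = a_not = b_ex = b_not = 0
    for key, dom in dominance.items():
        if dom == DominanceClass.EQUIVALENT:
            continue
        is_ex = bool(
            exhausted_fraction.get(key, 0.0) > exhausted_cell_fraction_threshold
        )
        if dom == DominanceClass.A_DOMINANT:
            a_ex, a_not = a_ex + is_ex, a_not + (not is_ex)
        else:
            b_ex, b_not = b_ex + is_ex, b_not + (not is_ex)
    table = ((a_ex, a_not), (b_ex, b_not))
    odds = (
        (a_ex * b_not) / (a_not * b_ex)
        if a_not * b_ex > 0
        else float("inf") if a_ex * b_not > 0 else float("nan")
    )
    return {
        "table": table,
        "n_a_dominant": a_ex + a_not,
        "n_b_dominant": b_ex + b_not,
        "odds_ratio": odds,
        "p_value": fisher_exact(table),
    }


@dataclass(frozen=True)
class MarkerRule:
    label: str
    required: tuple
    excluded: tuple = ()


#: Rule table of canonical T-cell marker combinations.  A cluster gets a
#: label when all required markers are high and all excluded markers low;
#: the only exclusion is CD8A for cytotoxic CD4 cells (CD4/GZMA combined
#: with lack of CD8A).
DEFAULT_MARKER_RULES = (
    MarkerRule("exhausted_cd8", ("CD8A", "PDCD1", "HAVCR2")),
    MarkerRule("follicular_helper_cd4", ("CD4", "CD200", "CXCL13")),
    MarkerRule("regulatory_t", ("CD4", "FOXP3")),
    MarkerRule("cytotoxic_cd4", ("CD4", "GZMA"), ("CD8A",)),
    MarkerRule("memory_cd8", ("CD8A", "EOMES")),
    MarkerRule("activated_cd8", ("CD8A", "CD69")),
    MarkerRule("activated_memory_cd4", ("CD4", "CD69")),
    MarkerRule("naive_cd8", ("CD8A", "CCR7")),
    MarkerRule("naive_cd4", ("CD4", "CCR7")),
    MarkerRule("t_cell", ("CD3D", "CD3E", "CD2")),
)


def annotate_clusters(
    cluster_mean_expr: pd.DataFrame,
    rules: Sequence[MarkerRule] = DEFAULT_MARKER_RULES,
    dichotomize: str = "mean",
) -> dict[str, str]:
    """Label clusters from marker-gene means (clusters x genes matrix).

    A gene is "high" in a cluster when its mean there strictly exceeds
    the across-cluster centre for that gene (the mean by default; a
    marker that is high in a majority of clusters — CD4 spans five of
    the nine canonical T-cell states — would sit *at* the median in its
    weakest positive cluster, so the strict median rule cannot label it;
    ``dichotomize="median"`` remains available).  Each cluster receives
    the first rule (in rule-table order, most specific first) whose
    required markers are all high and excluded markers all low;
    otherwise ``unassigned``.  Rules naming genes absent from the matrix
    are skipped with a warning.  Deterministic given the rule table.
    """
    if dichotomize not in ("mean", "median"):
        raise ValueError("dichotomize must be 'mean' or 'median'")
    centre = getattr(cluster_mean_expr, dichotomize)(axis=0)
    high = cluster_mean_expr.gt(centre, axis=1)
    labels: dict[str, str] = {}
    for cluster in cluster_mean_expr.index:
        label = "unassigned"
        for rule in rules:
            genes = set(rule.required) | set(rule.excluded)
            absent = genes - set(cluster_mean_expr.columns)
            if absent:
                warnings.warn(
                    f"rule {rule.label!r} skipped: missing genes {sorted(absent)}"
                )
                continue
            if all(high.loc[cluster, g] for g in rule.required) and not any(
                high.loc[cluster, g] for g in rule.excluded
            ):
                label = rule.label
                break
        labels[str(cluster)] = label
    return labels
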