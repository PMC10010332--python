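"""Readers and writers for the tabular dialects the pipeline consumes.

All tables are plain text (TSV/CSV/JSON/FASTA).  Positions are 1-based
throughout (VCF convention).  The synthetic-data generators emit exactly
these dialects, so end-to-end runs need no adapters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .response import LesionObservation, PatientRecord
from .tcr import CellRecord, ChainEvidence
from .variants import Consequence, FilterReport, VariantCall

__all__ = [
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "write_filter_report",
    "read_sites_tsv",
    "write_lrr_track",
    "read_contigs_csv",
    "read_cell_metadata_csv",
    "read_protein_fasta",
    "read_binding_tsv",
    "read_lesions_csv",
    "read_patients_csv",
    "load_patient_records",
]

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "tumor_alt_fwd", "tumor_alt_rev", "tumor_ref_fwd", "tumor_ref_rev",
    "normal_alt", "normal_total", "in_population_db", "consequence",
]


def _call_from_row(row) -> VariantCall:
    cons = row.get("consequence")
    return VariantCall(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        tumor_alt_fwd=int(row["tumor_alt_fwd"]),
        tumor_alt_rev=int(row["tumor_alt_rev"]),
        tumor_ref_fwd=int(row["tumor_ref_fwd"]),
        tumor_ref_rev=int(row["tumor_ref_rev"]),
        normal_alt=int(row.get("normal_alt", 0)),
        normal_total=int(row.get("normal_total", 0)),
        in_population_db=bool(row.get("in_population_db", False)),
        consequence=Consequence(cons) if isinstance(cons, str) else None,
    )


def read_variants_tsv(path: PathLike) -> list[VariantCall]:
    """Read candidate calls from the documented TSV dialect.

    Required columns: chrom, pos, ref, alt and the four per-strand tumor
    counts; normal_alt/normal_total/in_population_db/consequence are
    optional.  Multi-allelic rows (comma in alt) are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    required = VARIANT_COLUMNS[:8]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns: {missing}")
    return [_call_from_row(row) for _, row in df.iterrows()]


def variants_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "tumor_alt_fwd": c.tumor_alt_fwd,
                "tumor_alt_rev": c.tumor_alt_rev,
                "tumor_ref_fwd": c.tumor_ref_fwd,
                "tumor_ref_rev": c.tumor_ref_rev,
                "normal_alt": c.normal_alt, "normal_total": c.normal_total,
                "in_population_db": c.in_population_db,
                "consequence": c.consequence.value if c.consequence else None,
            }
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants_tsv(calls: Iterable[VariantCall], path: PathLike) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_variants_vcf(
    path: PathLike, tumor_sample: str, normal_sample: str
) -> list[VariantCall]:
    """Read a tumor/normal pair from a VCF.

    Per-strand tumor alt counts come from a 4-field ``SB`` FORMAT entry
    (ref-fwd, ref-rev, alt-fwd, alt-rev) when present; otherwise ``AD``
    allele depths are split evenly between strands (and the strand
    criterion loses its meaning — prefer inputs carrying SB).  Records
    must be bi-allelic; split multi-allelic sites upstream
    (e.g. ``bcftools norm -m-``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx, n_idx = samples.index(tumor_sample), samples.index(normal_sample)
    except ValueError as exc:
        raise ValueError(f"sample not in VCF ({samples}): {exc}") from exc
    calls = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "split to one alt per row first"
            )
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"no AD field at {rec.CHROM}:{rec.POS}")
        sb = rec.format("SB")
        if sb is not None and sb.shape[1] == 4:
            rf, rr, af, ar = (int(x) for x in sb[t_idx])
        else:
            t_ref, t_alt = int(ad[t_idx][0]), int(ad[t_idx][1])
            rf, rr = t_ref - t_ref // 2, t_ref // 2
            af, ar = t_alt - t_alt // 2, t_alt // 2
        n_ref, n_alt = int(ad[n_idx][0]), int(ad[n_idx][1])
        calls.append(
            VariantCall(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                tumor_alt_fwd=af, tumor_alt_rev=ar,
                tumor_ref_fwd=rf, tumor_ref_rev=rr,
                normal_alt=n_alt, normal_total=n_ref + n_alt,
            )
        )
    return calls


def write_filter_report(
    report: FilterReport, retained_path: PathLike, report_path: PathLike
) -> None:
    """Write retained calls as TSV and the rejection tally as JSON."""
    write_variants_tsv(report.retained, retained_path)
    payload = {
        "n_input": report.n_input,
        "n_retained": len(report.retained),
        "n_rejected": len(report.rejected),
        "tally": report.tally,
    }
    Path(report_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sites_tsv(path: PathLike) -> pd.DataFrame:
    """SNP-site table: chrom, pos, normal_vaf, normal_depth, tumor_depth,
    gc_fraction (the last may be absent if computed from a FASTA)."""
    return pd.read_csv(path, sep="\t")


def write_lrr_track(track: pd.DataFrame, path: PathLike) -> None:
    cols = ["chrom", "pos", "lrr", "lrr_windowed"]
    track[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_contigs_csv(path: PathLike) -> list[ChainEvidence]:
    """10x-style filtered contig annotations (barcode, chain, v_gene,
    j_gene, cdr3, cdr3_nt, umis)."""
    df = pd.read_csv(path)
    return [
        ChainEvidence(
            barcode=str(r["barcode"]), chain=str(r["chain"]),
            v_gene=str(r["v_gene"]), j_gene=str(r["j_gene"]),
            cdr3_nt=str(r["cdr3_nt"]),
            cdr3_aa=str(r.get("cdr3", "") or ""),
            umis=int(r["umis"]),
        )
        for _, r in df.iterrows()
    ]


def read_cell_metadata_csv(path: PathLike) -> list[CellRecord]:
    """Cell metadata: barcode, sample, mito_fraction, n_genes, cluster."""
    df = pd.read_csv(path)
    return [
        CellRecord(
            barcode=str(r["barcode"]), sample=str(r["sample"]),
            mito_fraction=float(r["mito_fraction"]),
            n_genes=int(r["n_genes"]),
            cluster=str(r.get("cluster", "unassigned")),
        )
        for _, r in df.iterrows()
    ]


def read_protein_fasta(path: PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_binding_tsv(path: PathLike) -> dict[tuple[str, str], float]:
    """NetMHCpan-style table: peptide, allele, percent_rank."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r["peptide"]), str(r["allele"])): float(r["percent_rank"])
        for _, r in df.iterrows()
    }


def read_lesions_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def read_patients_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def load_patient_records(
    lesions: pd.DataFrame, patients: pd.DataFrame
) -> list[PatientRecord]:
    """Join the lesions and patients tables into PatientRecord objects."""
    by_patient: dict[str, list[LesionObservation]] = {}
    for _, r in lesions.iterrows():
        obs = LesionObservation(
            patient=str(r["patient"]), lesion=str(r["lesion"]),
            time_days=float(r["time_days"]),
            diameter_mm=float(r["diameter_mm"]),
            is_new_lesion=bool(r.get("is_new", False)),
        )
        by_patient.setdefault(obs.patient, []).append(obs)
    records = []
    for _, r in patients.iterrows():
        pid = str(r["patient"])
        records.append(
            PatientRecord(
                patient=pid,
                cancer_type=str(r["cancer_type"]),
                lesions=by_patient.get(pid, []),
                pfs_days=float(r["pfs_days"]),
                pfs_event=bool(r["pfs_event"]),
                os_days=float(r["os_days"]),
                os_event=bool(r["os_event"]),
                local_therapy=bool(r.get("local_therapy", False)),
            )
        )
    return records
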