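"""Mutant 9-mer enumeration and interlesion neoantigen overlap.

Around each nonsynonymous substitution, every 9-residue window of the
mutated protein that covers the altered position is a candidate MHC
class I epitope.  Binding predictions are consumed from a
NetMHCpan-style table (peptide, allele, %Rank); candidates at or below
the strong-binder threshold (%Rank <= 0.5 by default) are retained and
partitioned into lesion-private and shared sets.

A neoantigen's identity for overlap purposes is the (peptide, allele)
pair, not the source mutation: distinct mutations can yield identical
peptides.  Counts keyed by source mutation are also emitted.

Only single-residue substitutions are supported; frameshift- or
fusion-derived peptides and lengths other than 9 are out of scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence
import warnings

__all__ = [
    "MutationKey",
    "NeoantigenCandidate",
    "VennPartition",
    "enumerate_mutant_9mers",
    "filter_strong_binders",
    "venn_partition",
    "neoantigen_burden_by_lesion",
    "pseudo_rank",
]

PEPTIDE_LENGTH = 9
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationKey:
    """Identity of a mutation plus optional protein context.

    Equality and hashing use only the genomic tuple
    (chrom, pos, ref, alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    protein_id: Optional[str] = None
    protein_pos: Optional[int] = None  # 1-based residue index
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def __eq__(self, other) -> bool:
        if not isinstance(other, MutationKey):
            return NotImplemented
        return (self.chrom, self.pos, self.ref, self.alt) == (
            other.chrom, other.pos, other.ref, other.alt
        )

    def __hash__(self) -> int:
        return hash((self.chrom, self.pos, self.ref, self.alt))


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A mutant 9-mer with its MHC allele and NetMHCpan-style %Rank."""

    peptide: str
    mhc_allele: str
    percent_rank: float
    source: Optional[MutationKey] = None

    def __post_init__(self) -> None:
        if len(self.peptide) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide must be {PEPTIDE_LENGTH} residues")
        if self.percent_rank < 0:
            raise ValueError("percent_rank must be non-negative")


@dataclass(frozen=True)
class VennPartition:
    only_a: frozenset
    shared: frozenset
    only_b: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.shared), len(self.only_b))


def enumerate_mutant_9mers(
    protein_seq: str, p: int, alt_aa: str, ref_aa: Optional[str] = None
) -> list[str]:
    """All 9-mers of the mutated protein that cover the altered residue.

    ``p`` is the 1-based mutated position; the residue there is replaced
    with ``alt_aa`` and every length-9 window whose span includes ``p``
    is returned (window starts ``max(1, p-8)`` .. ``min(p, L-8)``) —
    between 1 (terminal positions) and 9 (interior) peptides.  Proteins
    shorter than 9 residues yield an empty list with a warning.
    """
    L = len(protein_seq)
    if not 1 <= p <= L:
        raise ValueError(f"position {p} outside protein of length {L}")
    if alt_aa not in AA_ALPHABET:
        raise ValueError(f"alt_aa {alt_aa!r} is not a standard residue")
    if ref_aa is not None and ref_aa == alt_aa:
        raise ValueError("alt_aa equals ref_aa: not a substitution")
    if ref_aa is not None and protein_seq[p - 1] != ref_aa:
        raise ValueError(
            f"reference residue mismatch at {p}: "
            f"sequence has {protein_seq[p - 1]!r}, expected {ref_aa!r}"
        )
    if L < PEPTIDE_LENGTH:
        warnings.warn(f"protein of length {L} < 9: no peptides enumerated")
        return []
    mutated = protein_seq[: p - 1] + alt_aa + protein_seq[p:]
    first = max(1, p - (PEPTIDE_LENGTH - 1))
    last = min(p, L - PEPTIDE_LENGTH + 1)
    return [mutated[s - 1 : s - 1 + PEPTIDE_LENGTH] for s in range(first, last + 1)]


def filter_strong_binders(
    candidates: Iterable[NeoantigenCandidate], rank_threshold: float = 0.5
) -> list[NeoantigenCandidate]:
    """Keep strong binders (%Rank <= threshold, boundary inclusive),
    deduplicating identical (peptide, allele) pairs at the minimal rank."""
    best: dict[tuple[str, str], NeoantigenCandidate] = {}
    for c in candidates:
        if c.percent_rank < 0:
            raise ValueError("negative percent_rank")
        if c.percent_rank > rank_threshold:
            continue
        key = (c.peptide, c.mhc_allele)
        if key not in best or c.percent_rank < best[key].percent_rank:
            best[key] = c
    return list(best.values())


def venn_partition(set_a: Iterable, set_b: Iterable) -> VennPartition:
    """Two-set partition into (only A, shared, only B)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return VennPartition(only_a=a - b, shared=a & b, only_b=b - a)


def pseudo_rank(peptide: str, allele: str, strong_fraction: float = 0.02) -> float:
    """Deterministic stand-in for a binding predictor (synthetic ranks).

    Hashes (peptide, allele) to a %Rank in [0, 100); a ``strong_fraction``
    of pairs land uniformly in [0, 0.5].  Used by tests and examples where
    real binding predictions are unavailable; not a binding model.
    """
    h = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
    u = int.from_bytes(h[:8], "big") / 2**64
    if u < strong_fraction:
        return (u / strong_fraction) * 0.5
    return 0.5 + (u - strong_fraction) / (1 - strong_fraction) * 99.5


def neoantigen_burden_by_lesion(
    mutations_by_lesion: Mapping[str, Sequence[MutationKey]],
    protein_seqs: Mapping[str, str],
    binding_table: Mapping[tuple[str, str], float],
    alleles: Sequence[str],
    rank_threshold: float = 0.5,
) -> dict:
    """Per-lesion strong-binder counts and the interlesion partition.

    For each lesion, enumerates mutant 9-mers from its mutations (which
    need protein context and a sequence in ``protein_seqs``), looks up
    %Rank for every (peptide, allele) pair in ``binding_table``, and keeps
    strong binders.  A neoantigen is shared iff its (peptide, allele) key
    passes the threshold in both lesions.  Peptide/allele pairs missing
    from the binding table are excluded from counts and listed in the
    coverage report.  Exactly two lesions are required for the partition.

    Returns a dict with per-lesion candidate lists, (peptide, allele) and
    mutation-keyed partitions, and the missing-pair coverage report.
    """
    if len(mutations_by_lesion) != 2:
        raise ValueError("exactly two lesions required for a partition")
    per_lesion: dict[str, list[NeoantigenCandidate]] = {}
    missing: set[tuple[str, str]] = set()
    for lesion, muts in mutations_by_lesion.items():
        cands = []
        for m in muts:
            if m.protein_id is None or m.protein_pos is None or m.alt_aa is None:
                raise ValueError(f"mutation {m} lacks protein context")
            seq = protein_seqs.get(m.protein_id)
            if seq is None:
                raise ValueError(f"no protein sequence for {m.protein_id}")
            for pep in enumerate_mutant_9mers(seq, m.protein_pos, m.alt_aa, m.ref_aa):
                for allele in alleles:
                    rank = binding_table.get((pep, allele))
                    if rank is None:
                        missing.add((pep, allele))
                        continue
                    cands.append(NeoantigenCandidate(pep, allele, rank, source=m))
        per_lesion[lesion] = filter_strong_binders(cands, rank_threshold)

    (name_a, strong_a), (name_b, strong_b) = per_lesion.items()
    keys_a = {(c.peptide, c.mhc_allele) for c in strong_a}
    keys_b = {(c.peptide, c.mhc_allele) for c in strong_b}
    mut_a = {c.source for c in strong_a}
    mut_b = {c.source for c in strong_b}
    return {
        "lesions": (name_a, name_b),
        "strong_binders": per_lesion,
        "counts": {name_a: len(keys_a), name_b: len(keys_b)},
        "peptide_partition": venn_partition(keys_a, keys_b),
        "mutation_partition": venn_partition(mut_a, mut_b),
        "missing_pairs": sorted(missing),
    }
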