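"""Profile-HMM hit filtering for enzyme-family mining.

The default policy finds indoleamine 2,3-dioxygenases (IDO, Pfam PF01231):
a hit is kept when its model accession matches, the matched protein is at
least 350 residues long, and the full-sequence E-value is at most 1e-30.
Both thresholds are inclusive.  Kept hits are counted per genome (distinct
proteins, so multi-domain proteins count once) and used to flag the gene
clusters that contain a target enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import ClusterRecord, DomainHit

__all__ = [
    "FilterPolicy",
    "filter_hits",
    "count_per_genome",
    "flag_target_clusters",
    "hits_report",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusive thresholds applied to per-domain hmmsearch hits."""

    model_accession: str = "PF01231"
    min_subject_length: int = 350
    max_evalue: float = 1e-30

    def __post_init__(self) -> None:
        if self.min_subject_length < 1:
            raise ValueError("min_subject_length must be >= 1")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")

    def keeps(self, hit: DomainHit) -> bool:
        return (
            hit.model_accession == self.model_accession
            and hit.subject_length >= self.min_subject_length
            and hit.full_seq_evalue <= self.max_evalue
        )


def filter_hits(
    hits: list[DomainHit], policy: FilterPolicy | None = None
) -> list[DomainHit]:
    """Keep exactly the hits satisfying the policy, preserving input order."""
    policy = policy or FilterPolicy()
    return [h for h in hits if policy.keeps(h)]


def count_per_genome(hits: list[DomainHit]) -> dict[str, int]:
    """Distinct target proteins per genome among (already filtered) hits."""
    proteins: dict[str, set[str]] = {}
    for h in hits:
        proteins.setdefault(h.genome_id, set()).add(h.protein_id)
    return {g: len(p) for g, p in sorted(proteins.items())}


def flag_target_clusters(
    clusters: list[ClusterRecord], target_proteins: set[str]
) -> set[str]:
    """Ids of clusters containing at least one gene from the target set."""
    return {
        c.cluster_id
        for c in clusters
        if any(pid in target_proteins for pid in c.protein_ids())
    }


def hits_report(
    hits: list[DomainHit], policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Per-hit table with a ``kept`` flag under the policy."""
    policy = policy or FilterPolicy()
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "protein_id": h.protein_id,
                "model_accession": h.model_accession,
                "length": h.subject_length,
                "evalue": h.full_seq_evalue,
                "kept": policy.keeps(h),
            }
            for h in hits
        ],
        columns=[
            "genome_id",
            "protein_id",
            "model_accession",
            "length",
            "evalue",
            "kept",
        ],
    )
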