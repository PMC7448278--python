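"""Core record types shared across the toolkit.

A :class:`ClusterRecord` is the canonical in-memory form of one biosynthetic
gene cluster (BGC): its ordered protein-domain array, the amino-acid
sequences of its backbone-enzyme domains (adenylation, condensation,
thiolation, ketosynthase, ...), and its protein complement.  A
:class:`DomainHit` is one row of an hmmsearch per-domain table (domtblout)
used for enzyme-family mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "ValidationError",
    "DomainHit",
    "ClusterRecord",
]

#: The 20 proteinogenic residues plus X (unknown), the alphabet accepted in
#: backbone-domain and protein sequences.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ValidationError(ValueError):
    """A record violates its documented invariants."""


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit row from an hmmsearch tabular report.

    Coordinates are 1-based inclusive (HMMER convention).  ``subject_length``
    is the full length of the matched protein (the domtblout ``tlen``
    column), which is what length-based filter policies test.
    """

    protein_id: str
    genome_id: str
    model_accession: str
    model_name: str
    full_seq_evalue: float
    bitscore: float
    subject_length: int
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.env_start < 1:
            raise ValidationError(f"env_start must be >= 1, got {self.env_start}")
        if self.env_end < self.env_start:
            raise ValidationError(
                f"env_end ({self.env_end}) < env_start ({self.env_start})"
            )
        if self.subject_length < self.env_end:
            raise ValidationError(
                f"subject_length ({self.subject_length}) < env_end ({self.env_end})"
            )
        if self.full_seq_evalue < 0:
            raise ValidationError(f"negative E-value: {self.full_seq_evalue}")


def _check_sequence(seq: str, where: str) -> None:
    bad = set(seq.upper()) - AMINO_ACIDS
    if bad:
        raise ValidationError(
            f"{where}: invalid residue(s) {sorted(bad)} (alphabet is the 20 "
            "amino acids plus X)"
        )
    if not seq:
        raise ValidationError(f"{where}: empty sequence")


@dataclass
class ClusterRecord:
    """One biosynthetic gene cluster.

    Parameters
    ----------
    cluster_id, genome_id:
        Identifiers; ``cluster_id`` must be unique within a manifest.
    product_class:
        Free-text backbone class (e.g. ``"NRPS"``).
    domain_array:
        Ordered list of protein-domain names across the cluster's genes,
        e.g. ``["AMP-binding", "PCP", "Condensation", ...]``.  May be empty.
    backbone_domains:
        Map from backbone-domain type to the amino-acid sequences of each
        copy of that domain, in gene order (e.g. two adenylation domains
        give two ``"AMP-binding"`` entries).
    proteins:
        ``(protein_id, sequence)`` pairs for the cluster's genes.
    """

    cluster_id: str
    genome_id: str
    product_class: str = ""
    domain_array: list[str] = field(default_factory=list)
    backbone_domains: dict[str, list[str]] = field(default_factory=dict)
    proteins: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cluster_id:
            raise ValidationError("cluster_id must be non-empty")
        for dtype, seqs in self.backbone_domains.items():
            for i, seq in enumerate(seqs):
                _check_sequence(seq, f"{self.cluster_id}/backbone_domains[{dtype}][{i}]")

    @property
    def domain_set(self) -> frozenset[str]:
        """The deduplicated protein-domain content used for Jaccard similarity."""
        return frozenset(self.domain_array)

    def protein_ids(self) -> list[str]:
        return [pid for pid, _ in self.proteins]
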