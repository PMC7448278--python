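"""Adenylation-domain substrate-specificity codes.

Nonribosomal peptide synthetase adenylation (A) domains select their amino
acid substrate with a small set of binding-pocket residues.  Reading those
residues off at reference positions of the phenylalanine-activating
A-domain of gramicidin S synthetase (GrsA) yields the classic
"specificity code" (Stachelhaus code): A-domains with similar codes tend to
activate similar substrates.

Here a query A-domain is globally aligned to the reference synthetase
sequence and the query residues in the alignment columns of the configured
reference positions are reported, ``-`` where the query has a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import ClusterRecord
from .similarity import AlignmentParams, global_align

__all__ = [
    "DEFAULT_POSITIONS",
    "SpecificityCode",
    "extract_code",
    "code_identity",
    "code_table",
]

#: The ten canonical specificity positions in GrsA A-domain numbering
#: (binding-pocket residues lining the substrate, plus the invariant
#: C-terminal lysine).
DEFAULT_POSITIONS = (235, 236, 239, 278, 299, 301, 322, 330, 331, 517)


@dataclass(frozen=True)
class SpecificityCode:
    """Residues of one A-domain at the reference-defined pocket positions."""

    domain_id: str
    residues: str
    reference_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.reference_positions):
            raise ValueError(
                "residues length must equal number of reference positions"
            )

    @property
    def is_gap_free(self) -> bool:
        return "-" not in self.residues


def extract_code(
    query: str,
    reference: str,
    positions: tuple[int, ...] | list[int] = DEFAULT_POSITIONS,
    domain_id: str = "",
    params: AlignmentParams | None = None,
) -> SpecificityCode:
    """Read the query's residues at 1-based reference positions.

    The query is aligned globally to the reference; for each reference
    position the query residue in that alignment column is reported, ``-``
    when the query is gapped there (e.g. a truncation).
    """
    positions = tuple(int(p) for p in positions)
    for p in positions:
        if not 1 <= p <= len(reference):
            raise ValueError(
                f"reference position {p} outside 1..{len(reference)}"
            )
    aln = global_align(reference, query, params)
    wanted = set(positions)
    by_pos: dict[int, str] = {}
    ref_pos = 0
    for ref_char, q_char in zip(aln.a, aln.b):
        if ref_char != "-":
            ref_pos += 1
            if ref_pos in wanted:
                by_pos[ref_pos] = q_char if q_char != "-" else "-"
    residues = "".join(by_pos[p] for p in positions)
    return SpecificityCode(
        domain_id=domain_id, residues=residues, reference_positions=positions
    )


def code_identity(a: SpecificityCode, b: SpecificityCode) -> float:
    """Fraction of positions with identical residues; gaps match nothing."""
    if a.reference_positions != b.reference_positions:
        raise ValueError("codes use different reference positions")
    n = len(a.residues)
    matches = sum(
        1 for x, y in zip(a.residues, b.residues) if x == y and x != "-"
    )
    return matches / n


def code_table(
    clusters: list[ClusterRecord],
    reference: str,
    positions: tuple[int, ...] | list[int] = DEFAULT_POSITIONS,
    adomain_type: str = "AMP-binding",
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Specificity codes of every A-domain in a cluster set.

    One row per adenylation domain, labeled ``<cluster>|A_<k>`` in gene
    order within each cluster; clusters are processed in input order.
    """
    rows = []
    for c in clusters:
        for k, seq in enumerate(c.backbone_domains.get(adomain_type, []), start=1):
            code = extract_code(
                seq,
                reference,
                positions,
                domain_id=f"{c.cluster_id}|A_{k}",
                params=params,
            )
            rows.append(
                {
                    "domain_id": code.domain_id,
                    "cluster_id": c.cluster_id,
                    "domain_index": k,
                    "code": code.residues,
                }
            )
    return pd.DataFrame(
        rows, columns=["domain_id", "cluster_id", "domain_index", "code"]
    )
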