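"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* **Cluster manifest** (JSON): canonical BGC input —
  ``{"clusters": [{"cluster_id", "genome_id", "product_class",
  "domain_array": [...], "backbone_domains": {"type": [seq, ...]},
  "proteins": [{"id", "seq"}]}]}``.
* **domtblout**: the 23-column HMMER3 per-domain tabular report from
  hmmsearch.  Because the format has no genome column, the free-text
  description column may carry a ``genome=<id>`` token; it is parsed into
  :attr:`DomainHit.genome_id` (empty string otherwise).
* **FASTA** (protein), **Newick** with branch lengths, TSV edge lists and
  family tables.

Readers never silently drop data rows: a malformed row raises with its
line number.
"""

from __future__ import annotations

import io as _io
import json
import re
from pathlib import Path

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .families import Dendrogram, GCFAssignment, SINGLETON
from .records import ClusterRecord, DomainHit, ValidationError
from .similarity import SimilarityEdge

__all__ = [
    "ParseError",
    "read_domtblout",
    "write_domtblout",
    "read_cluster_manifest",
    "write_cluster_manifest",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "read_newick",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_family_table",
]


class ParseError(ValueError):
    """A data file row could not be parsed; the message names the line."""


_GENOME_RE = re.compile(r"genome=(\S+)")

# domtblout column indices (whitespace-split, 23rd column = free text):
# 0 target name, 1 target accession, 2 tlen, 3 query name, 4 query accession,
# 5 qlen, 6 full-seq E-value, 7 full-seq score, 8 full-seq bias, 9 dom #,
# 10 dom total, 11 c-Evalue, 12 i-Evalue, 13 dom score, 14 dom bias,
# 15 hmm from, 16 hmm to, 17 ali from, 18 ali to, 19 env from, 20 env to,
# 21 acc, 22.. description of target
_N_FIXED_COLS = 22


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse an hmmsearch ``--domtblout`` report into :class:`DomainHit` rows.

    Lines beginning with ``#`` are comments.  Raises :class:`ParseError`
    (naming the line number) on rows with too few columns or unparsable
    numerics, and ``FileNotFoundError`` on a missing file.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < _N_FIXED_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_N_FIXED_COLS} columns, "
                    f"got {len(cols)}"
                )
            description = " ".join(cols[_N_FIXED_COLS:])
            m = _GENOME_RE.search(description)
            try:
                hit = DomainHit(
                    protein_id=cols[0],
                    genome_id=m.group(1) if m else "",
                    model_accession=cols[4],
                    model_name=cols[3],
                    full_seq_evalue=float(cols[6]),
                    bitscore=float(cols[7]),
                    subject_length=int(cols[2]),
                    env_start=int(cols[19]),
                    env_end=int(cols[20]),
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domtblout(hits: list[DomainHit], path: str | Path) -> None:
    """Write hits back out in the 23-column domtblout layout.

    Columns the :class:`DomainHit` model does not carry (query length,
    per-domain statistics, alignment coordinates) are filled with
    placeholders consistent with the envelope coordinates, so files
    round-trip through :func:`read_domtblout`.
    """
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            desc = f"genome={h.genome_id}" if h.genome_id else "-"
            fh.write(
                f"{h.protein_id} - {h.subject_length} {h.model_name} "
                f"{h.model_accession} 0 {h.full_seq_evalue:.10g} "
                f"{h.bitscore:.1f} 0.0 1 1 {h.full_seq_evalue:.10g} "
                f"{h.full_seq_evalue:.10g} {h.bitscore:.1f} 0.0 "
                f"1 {h.env_end - h.env_start + 1} "
                f"{h.env_start} {h.env_end} {h.env_start} {h.env_end} "
                f"0.99 {desc}\n"
            )


def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise ValidationError(f"{where}: missing field {key!r}")
    return obj[key]


def read_cluster_manifest(path: str | Path) -> list[ClusterRecord]:
    """Read the canonical JSON cluster manifest.

    Every record is validated against the :class:`ClusterRecord`
    invariants; duplicate ``cluster_id`` values are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    clusters_raw = _require(doc, "clusters", str(path))
    records: list[ClusterRecord] = []
    seen: set[str] = set()
    for i, c in enumerate(clusters_raw):
        where = f"{path}: clusters[{i}]"
        cid = _require(c, "cluster_id", where)
        if cid in seen:
            raise ValidationError(f"{where}: duplicate cluster_id {cid!r}")
        seen.add(cid)
        backbone = c.get("backbone_domains", {})
        if not isinstance(backbone, dict):
            raise ValidationError(f"{where}: backbone_domains must be an object")
        proteins = [
            (_require(p, "id", f"{where}.proteins[{k}]"),
             _require(p, "seq", f"{where}.proteins[{k}]"))
            for k, p in enumerate(c.get("proteins", []))
        ]
        records.append(
            ClusterRecord(
                cluster_id=cid,
                genome_id=_require(c, "genome_id", where),
                product_class=c.get("product_class", ""),
                domain_array=list(c.get("domain_array", [])),
                backbone_domains={k: list(v) for k, v in backbone.items()},
                proteins=proteins,
            )
        )
    return records


def write_cluster_manifest(clusters: list[ClusterRecord], path: str | Path) -> None:
    """Write clusters as a JSON manifest (stable key order, 2-space indent)."""
    doc = {
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "genome_id": c.genome_id,
                "product_class": c.product_class,
                "domain_array": c.domain_array,
                "backbone_domains": c.backbone_domains,
                "proteins": [{"id": pid, "seq": seq} for pid, seq in c.proteins],
            }
            for c in clusters
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    """Serialize an ultrametric merge tree as Newick with branch lengths."""
    if tree is None:
        raise ValueError("empty tree")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(source: str | Path) -> Dendrogram:
    """Parse a Newick string or file back into a :class:`Dendrogram`.

    Node heights are reconstructed from root-to-node path lengths assuming
    an ultrametric tree (every leaf at height 0).
    """
    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            text = p.read_text()
        elif isinstance(source, str) and source.rstrip().endswith(";"):
            text = source
        else:
            raise FileNotFoundError(source)
    tree = Phylo.read(_io.StringIO(text), "newick")
    depths = tree.depths()
    total = max(depths.values()) if depths else 0.0

    def convert(clade) -> Dendrogram:
        height = total - depths[clade]
        if not clade.clades:
            return Dendrogram(height=0.0, name=clade.name)
        return Dendrogram(
            height=height, children=tuple(convert(c) for c in clade.clades)
        )

    return convert(tree.root)


_EDGE_COLS = ["cluster_a", "cluster_b", "seq_identity", "jaccard", "score"]


def write_edges_tsv(edges: list[SimilarityEdge], path: str | Path) -> None:
    """Write the all-pairs edge list as TSV with 6-decimal fractions."""
    df = pd.DataFrame(
        [
            (e.cluster_a, e.cluster_b, e.seq_identity, e.jaccard, e.score)
            for e in edges
        ],
        columns=_EDGE_COLS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_edges_tsv(path: str | Path) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        SimilarityEdge(
            cluster_a=str(r.cluster_a),
            cluster_b=str(r.cluster_b),
            seq_identity=float(r.seq_identity),
            jaccard=float(r.jaccard),
            score=float(r.score),
            n_matched_backbone_pairs=0,
        )
        for r in df.itertuples(index=False)
    ]


def write_family_table(assignment: GCFAssignment, path: str | Path) -> None:
    """Write the cluster → family table (``singleton`` for noise points)."""
    assignment.to_frame().to_csv(path, sep="\t", index=False)
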