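"""End-to-end run: manifest → similarity → families → dendrograms → reports.

Every stage's product is materialized to the output directory so
intermediate artifacts are inspectable, and a machine-readable
``summary.json`` records all parameters and counts.  Runs are
deterministic: rerunning the same config over the same inputs rewrites
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as gio
from .adomain import DEFAULT_POSITIONS, code_table
from .families import call_families, network_edges, upgma
from .mining import FilterPolicy, count_per_genome, filter_hits, flag_target_clusters, hits_report
from .similarity import ScoreWeights, similarity_matrix

__all__ = ["RunConfig", "PipelineError", "run_gcf_pipeline"]

log = logging.getLogger("gcfkit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    The defaults are the study constants: score weights 0.8 / 0.2, family
    epsilon 0.55 (network score threshold 0.45), and the PF01231 / 350
    residue / 1e-30 mining policy.
    """

    manifest: str | Path = "manifest.json"
    out_dir: str | Path = "gcfkit_out"
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    epsilon: float = 0.55
    min_members: int = 2
    score_threshold: float = 0.45
    domtblout: str | Path | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    adomain_reference: str | Path | None = None
    adomain_positions: tuple[int, ...] = DEFAULT_POSITIONS
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        kwargs = dict(doc)
        if "weights" in kwargs:
            kwargs["weights"] = ScoreWeights(**kwargs["weights"])
        if "filter_policy" in kwargs:
            kwargs["filter_policy"] = FilterPolicy(**kwargs["filter_policy"])
        if "adomain_positions" in kwargs:
            kwargs["adomain_positions"] = tuple(kwargs["adomain_positions"])
        return cls(**kwargs)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_gcf_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the summary dict.

    Outputs written to ``config.out_dir``: ``edges.tsv`` (all pairs),
    ``families.tsv``, ``dendrogram_all.nwk`` plus one Newick per family,
    ``adomain_codes.tsv`` and mining reports when configured, and
    ``summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    log.info(
        "gcfkit run: w_id=%s w_jac=%s epsilon=%s min_members=%s threshold=%s",
        config.weights.w_id,
        config.weights.w_jac,
        config.epsilon,
        config.min_members,
        config.score_threshold,
    )

    clusters = _stage("read_manifest")(gio.read_cluster_manifest)(config.manifest)
    if not clusters:
        raise PipelineError("stage 'read_manifest' failed: empty manifest")
    out.mkdir(parents=True, exist_ok=True)

    result = _stage("similarity")(similarity_matrix)(clusters, config.weights)
    gio.write_edges_tsv(result.edges, out / "edges.tsv")

    dist = result.distance()
    assignment = _stage("call_families")(call_families)(
        dist, epsilon=config.epsilon, min_members=config.min_members
    )
    gio.write_family_table(assignment, out / "families.tsv")

    edges = network_edges(result, config.score_threshold)

    tree = _stage("upgma")(upgma)(dist)
    gio.write_newick(tree, out / "dendrogram_all.nwk")
    for fam, members in sorted(assignment.families().items()):
        if len(members) >= 2:
            sub = dist.loc[members, members]
            gio.write_newick(upgma(sub), out / f"dendrogram_family_{fam}.nwk")

    summary: dict = {
        "parameters": {
            "w_id": config.weights.w_id,
            "w_jac": config.weights.w_jac,
            "epsilon": config.epsilon,
            "min_members": config.min_members,
            "score_threshold": config.score_threshold,
            "seed": config.seed,
        },
        "n_clusters": len(clusters),
        "n_edges_at_threshold": len(edges),
        "n_families": assignment.n_families,
        "n_singletons": len(assignment.singletons),
    }

    if config.domtblout is not None:
        hits = _stage("read_domtblout")(gio.read_domtblout)(config.domtblout)
        kept = filter_hits(hits, config.filter_policy)
        hits_report(hits, config.filter_policy).to_csv(
            out / "mining_hits.tsv", sep="\t", index=False, float_format="%.6g"
        )
        counts = count_per_genome(kept)
        with open(out / "mining_counts.tsv", "w") as fh:
            fh.write("genome_id\tn_target_proteins\n")
            for g, n in counts.items():
                fh.write(f"{g}\t{n}\n")
        flagged = sorted(
            flag_target_clusters(clusters, {h.protein_id for h in kept})
        )
        summary["mining"] = {
            "n_hits": len(hits),
            "n_kept": len(kept),
            "per_genome_counts": counts,
            "flagged_clusters": flagged,
        }

    if config.adomain_reference is not None:
        ref = gio.read_fasta(config.adomain_reference)
        if not ref:
            raise PipelineError("stage 'adomain' failed: empty reference FASTA")
        table = _stage("adomain")(code_table)(
            clusters, ref[0][1], config.adomain_positions
        )
        table.to_csv(out / "adomain_codes.tsv", sep="\t", index=False)
        summary["n_adomain_codes"] = len(table)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
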