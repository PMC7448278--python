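"""Synthetic fixtures with known ground truth.

Three generators cover every pipeline stage without any external data:

* :func:`simulate_families` — families of BGCs whose members share a
  mutated copy of a family archetype backbone (controlled within-family
  identity) and a core domain set plus per-member private domains
  (controlled within-family Jaccard), together with unrelated background
  singletons and the true partition.
* :func:`simulate_hit_table` — a domtblout file with planted rows that
  pass a :class:`~gcfkit.mining.FilterPolicy` and decoys that each violate
  at least one criterion, with per-row labels.
* :func:`mutate_sequence` — the point-substitution primitive behind the
  identity control.

All generators are fully deterministic under the configured seed.

Identity control: members are mutated from the archetype at per-site rate
``1 - sqrt(target)``, so two members' pairwise identity is ``target`` in
expectation (each site survives both branches with probability
``sqrt(target)²``; the small chance of two substitutions coinciding adds
about ``rate²/19``).  Jaccard control: the family core set of ``c``
domains plus ``m`` private domains per member gives pairwise Jaccard
``c / (c + 2m)``; ``m`` is chosen to meet the target in expectation, so
exact attainment is not guaranteed and realized values are documented
with tolerances in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_domtblout
from .mining import FilterPolicy
from .records import ClusterRecord, DomainHit

__all__ = [
    "AA20",
    "SimulationConfig",
    "GroundTruth",
    "HitTableTruth",
    "mutate_sequence",
    "random_sequence",
    "simulate_families",
    "simulate_hit_table",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Default NRPS architecture: A1-T1-C1-A2-T2-C2-T3 (two adenylation, two
#: condensation, three thiolation domains), plus a PKS and a DMAT
#: architecture so that distinct families get distinct backbones.
DEFAULT_ARCHETYPE_ARRAYS: tuple[tuple[str, ...], ...] = (
    (
        "AMP-binding",
        "PCP",
        "Condensation",
        "AMP-binding",
        "PCP",
        "Condensation",
        "PCP",
    ),
    ("PKS_KS", "PKS_AT", "PCP", "TE"),
    ("DMAT",),
    ("AMP-binding", "PCP", "TE"),
    ("PKS_KS", "PKS_AT", "PCP"),
)

#: Tailoring/accessory domain names used to build domain sets.
DEFAULT_DOMAIN_POOL: tuple[str, ...] = (
    "p450",
    "Methyltransf_2",
    "Methyltransf_3",
    "FAD_binding_3",
    "FAD_binding_4",
    "ABC_tran",
    "MFS_1",
    "Epimerase",
    "NAD_binding_4",
    "Aminotran_1_2",
    "Aminotran_3",
    "GST_N",
    "Abhydrolase_1",
    "Acetyltransf_1",
    "adh_short",
    "ADH_zinc_N",
    "Cu-oxidase",
    "Dioxygenase_C",
    "DUF3328",
    "Trp_halogenase",
    "Glycos_transf_1",
    "Ketoacyl-synt_C",
    "Lycopene_cycl",
    "Oxidored_FMN",
    "Peptidase_S9",
    "PhyH",
    "Prenyltrans",
    "SDR",
    "Sugar_tr",
    "Transferase",
    "Tyrosinase",
    "Amidase",
    "AMP-binding_C",
    "Asp_aminotransf",
    "Berberine",
    "CoA_transf_3",
    "Cys_Met_Meta_PP",
    "Flavin_Reduct",
    "GMC_oxred_N",
    "Isochorismatase",
    "2OG-FeII_Oxy",
    "AA_permease",
    "Acyl_transf_1",
    "Aldedh",
    "Alpha-amylase",
    "AA_kinase",
    "Carb_anhydrase",
    "Catalase",
    "Chitin_synth_2",
    "CorA",
    "Cupin_2",
    "Cytochrom_B561",
    "DAO",
    "EthD",
    "FMO-like",
    "Fungal_trans",
    "GFO_IDH_MocA",
    "Glyco_hydro_3",
    "HLH",
    "Hydrolase_4",
    "Lactamase_B",
    "Lipase_GDSL",
    "MatE",
    "NMO",
    "PaaA_PaaC",
    "Polysacc_synt",
    "Pyr_redox_2",
    "Questin_oxidase",
    "Reductase_C",
    "SnoaL",
    "Terpene_synth_C",
    "Thiolase_N",
    "TauD",
    "UbiA",
    "Zn_clus",
)


@dataclass
class SimulationConfig:
    """Parameters of a family simulation.

    ``within_identity`` / ``within_jaccard`` are the expected pairwise
    backbone identity and domain-set Jaccard between members of the same
    family; ``between_*`` are the corresponding expectations across
    families (low by construction: independent archetype sequences and
    disjoint core domain draws).  ``seed`` is mandatory — every run is
    reproducible byte for byte.
    """

    n_families: int = 2
    family_sizes: list[int] = field(default_factory=lambda: [3, 3])
    within_identity: float = 0.9
    between_identity: float = 0.05
    within_jaccard: float = 0.8
    between_jaccard: float = 0.1
    n_singletons: int = 2
    domain_pool: tuple[str, ...] = DEFAULT_DOMAIN_POOL
    archetype_domain_arrays: tuple[tuple[str, ...], ...] = DEFAULT_ARCHETYPE_ARRAYS
    core_tailoring_domains: int = 6
    seq_length_range: tuple[int, int] = (300, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes length must equal n_families")
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if not 0 <= self.between_identity < self.within_identity <= 1:
            raise ValueError(
                "need 0 <= between_identity < within_identity <= 1"
            )
        if not 0 <= self.between_jaccard < self.within_jaccard <= 1:
            raise ValueError("need 0 <= between_jaccard < within_jaccard <= 1")


@dataclass
class GroundTruth:
    """True partition of generated cluster ids.

    ``partition`` maps every cluster id to its family label; singletons get
    unique ``singleton:<id>`` labels, so the mapping is a full partition.
    """

    partition: dict[str, str]

    def family_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, lab in self.partition.items():
            out.setdefault(lab, []).append(cid)
        return out

    def to_labels(self, ids: list[str]) -> list[int]:
        labels = {lab: i for i, lab in enumerate(dict.fromkeys(self.partition.values()))}
        return [labels[self.partition[cid]] for cid in ids]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """A uniform random protein sequence over the 20 residues."""
    return "".join(rng.choice(list(AA20), size=length))


def mutate_sequence(
    seq: str, substitution_rate: float, rng: np.random.Generator
) -> str:
    """Substitute each position independently with the given probability.

    A substituted position always receives a *different* residue, so a rate
    of 1 changes every position.  Length is preserved (no indels).
    """
    if not 0 <= substitution_rate <= 1:
        raise ValueError("substitution rate must lie in [0, 1]")
    out = []
    for ch in seq:
        if rng.random() < substitution_rate:
            choices = AA20.replace(ch, "") if ch in AA20 else AA20
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _member_rate(target_identity: float) -> float:
    """Per-branch substitution rate so two mutated copies match at ~target."""
    return 1.0 - math.sqrt(target_identity)


def _pool_draw(
    pool: list[str], k: int, rng: np.random.Generator, what: str
) -> list[str]:
    if k > len(pool):
        raise ValueError(
            f"domain_pool too small: need {k} more domains for {what}, "
            f"{len(pool)} left"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    picked = [pool[i] for i in sorted(idx)]
    for name in picked:
        pool.remove(name)
    return picked


def simulate_families(
    config: SimulationConfig,
) -> tuple[list[ClusterRecord], GroundTruth]:
    """Generate a cluster manifest with known family structure.

    Each family draws an archetype domain array (cycling through the
    configured architectures), archetype backbone sequences per domain
    type, and a core tailoring-domain set; members are point-mutated copies
    of the archetype with private tailoring domains appended.  Singletons
    draw everything independently.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pool = list(config.domain_pool)
    lo, hi = config.seq_length_range
    member_rate = _member_rate(config.within_identity)

    clusters: list[ClusterRecord] = []
    partition: dict[str, str] = {}

    # Family cores and singleton privates consume the global pool (keeping
    # between-cluster tailoring overlap at zero); per-member private domains
    # draw from a per-family copy of whatever remains, distinct within the
    # family but reusable across families.
    family_cores = [
        _pool_draw(pool, config.core_tailoring_domains, rng, f"family {f} core")
        for f in range(config.n_families)
    ]
    singleton_privates = [
        _pool_draw(pool, 4, rng, f"singleton S{s}")
        for s in range(config.n_singletons)
    ]

    for f in range(config.n_families):
        arch_array = list(
            config.archetype_domain_arrays[f % len(config.archetype_domain_arrays)]
        )
        backbone_types = list(dict.fromkeys(arch_array))
        copies = {t: arch_array.count(t) for t in backbone_types}
        arch_seqs = {
            t: [
                random_sequence(int(rng.integers(lo, hi + 1)), rng)
                for _ in range(copies[t])
            ]
            for t in backbone_types
        }
        core_tailoring = family_cores[f]
        core_size = len(set(arch_array)) + len(core_tailoring)
        j = config.within_jaccard
        m_private = max(0, round(core_size * (1 - j) / (2 * j))) if j > 0 else 3
        local_pool = list(pool)

        for member in range(config.family_sizes[f]):
            cid = f"F{f}_c{member}"
            mutated = {
                t: [mutate_sequence(s, member_rate, rng) for s in seqs]
                for t, seqs in arch_seqs.items()
            }
            private = _pool_draw(
                local_pool, m_private, rng, f"{cid} private domains"
            )
            domain_array = arch_array + core_tailoring + private
            proteins = [
                (f"{cid}_bb", "".join(s for seqs in mutated.values() for s in seqs))
            ] + [
                (f"{cid}_t{k}", random_sequence(120, rng))
                for k in range(len(core_tailoring))
            ]
            clusters.append(
                ClusterRecord(
                    cluster_id=cid,
                    genome_id=f"genome_F{f}_{member}",
                    product_class=_product_class(arch_array),
                    domain_array=domain_array,
                    backbone_domains=mutated,
                    proteins=proteins,
                )
            )
            partition[cid] = f"family_{f}"

    for s in range(config.n_singletons):
        cid = f"S{s}"
        arch_array = list(
            config.archetype_domain_arrays[
                (config.n_families + s) % len(config.archetype_domain_arrays)
            ]
        )
        backbone_types = list(dict.fromkeys(arch_array))
        seqs = {
            t: [
                random_sequence(int(rng.integers(lo, hi + 1)), rng)
                for _ in range(arch_array.count(t))
            ]
            for t in backbone_types
        }
        private = singleton_privates[s]
        clusters.append(
            ClusterRecord(
                cluster_id=cid,
                genome_id=f"genome_S{s}",
                product_class=_product_class(arch_array),
                domain_array=arch_array + private,
                backbone_domains=seqs,
                proteins=[
                    (f"{cid}_bb", "".join(x for v in seqs.values() for x in v))
                ],
            )
        )
        partition[cid] = f"singleton:{cid}"

    return clusters, GroundTruth(partition=partition)


def _product_class(arch_array: list[str]) -> str:
    if "AMP-binding" in arch_array:
        return "NRPS"
    if "PKS_KS" in arch_array:
        return "PKS"
    if "DMAT" in arch_array:
        return "DMAT"
    return "other"


@dataclass
class HitTableTruth:
    """Per-row labels of a simulated domain-hit table."""

    keep: dict[str, bool]
    reason: dict[str, str]
    copy_numbers: dict[str, int]

    @property
    def true_ids(self) -> set[str]:
        return {pid for pid, k in self.keep.items() if k}


def simulate_hit_table(
    n_true: int,
    n_decoys: int,
    policy: FilterPolicy | None = None,
    seed: int = 0,
    path: str | Path | None = None,
    n_genomes: int = 3,
) -> tuple[list[DomainHit], HitTableTruth]:
    """Plant ``n_true`` policy-passing rows among ``n_decoys`` violations.

    The first true row sits exactly on both inclusive boundaries (length =
    minimum, E-value = maximum).  Decoys cycle through the three violation
    modes — too short, E-value too high (the first just past the
    boundary), wrong model accession — and are labeled with their reason.
    True hits are distributed round-robin over ``n_genomes`` genomes so
    per-genome copy numbers are known.  When ``path`` is given, the table
    is also written as domtblout.
    """
    policy = policy or FilterPolicy()
    rng = np.random.default_rng(seed)
    hits: list[DomainHit] = []
    keep: dict[str, bool] = {}
    reason: dict[str, str] = {}
    copy_numbers: dict[str, int] = {}

    def _evalue_pass() -> float:
        return float(policy.max_evalue * 10 ** (-rng.uniform(1.0, 30.0)))

    def _length_pass() -> int:
        return int(policy.min_subject_length + rng.integers(10, 350))

    for i in range(n_true):
        pid = f"true_{i}"
        genome = f"g{i % n_genomes}"
        if i == 0:
            length, ev = policy.min_subject_length, policy.max_evalue
        else:
            length, ev = _length_pass(), _evalue_pass()
        hits.append(
            DomainHit(
                protein_id=pid,
                genome_id=genome,
                model_accession=policy.model_accession,
                model_name="IDO",
                full_seq_evalue=ev,
                bitscore=float(rng.uniform(120, 400)),
                subject_length=length,
                env_start=1,
                env_end=min(length, 340),
            )
        )
        keep[pid] = True
        reason[pid] = "boundary" if i == 0 else "pass"
        copy_numbers[genome] = copy_numbers.get(genome, 0) + 1

    modes = ("short", "evalue", "accession")
    for i in range(n_decoys):
        pid = f"decoy_{i}"
        genome = f"g{i % n_genomes}"
        mode = modes[i % len(modes)]
        length, ev, acc = _length_pass(), _evalue_pass(), policy.model_accession
        if mode == "short":
            length = int(rng.integers(80, policy.min_subject_length))
        elif mode == "evalue":
            ev = (
                float(policy.max_evalue * 1.0000001)
                if i < len(modes)
                else float(policy.max_evalue * 10 ** rng.uniform(1.0, 10.0))
            )
        else:
            acc = "PF00501"  # AMP-binding, a plausible off-target model
        hits.append(
            DomainHit(
                protein_id=pid,
                genome_id=genome,
                model_accession=acc,
                model_name="IDO" if acc == policy.model_accession else "AMP-binding",
                full_seq_evalue=ev,
                bitscore=float(rng.uniform(20, 120)),
                subject_length=length,
                env_start=1,
                env_end=min(length, 340),
            )
        )
        keep[pid] = False
        reason[pid] = mode

    order = rng.permutation(len(hits))
    hits = [hits[i] for i in order]
    if path is not None:
        write_domtblout(hits, path)
    return hits, HitTableTruth(keep=keep, reason=reason, copy_numbers=copy_numbers)
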