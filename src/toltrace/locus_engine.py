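"""Cluster role-bearing genes into loci and classify each genome's
Tol-Pal / Ton status.

The central genomic-context rule: a force transducer can only be called TolA
when it sits inside a gene cluster (or a "split" union of clusters) that
carries the minimal tol-pal complement — a motor pentamer and dimer, a
transducer, tolB and pal.  Transducers without that context are TonB
candidates.  Proximity is strand-agnostic: two role-bearing genes belong to
the same locus when they lie on the same replicon, within
``max_intervening + 1`` ranks and ``max_gap_bp`` base pairs of each other
(connected components of that relation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .config import RunConfig
from .formats_io import GeneRecord, SecondaryStructureProfile, ValidationError
from .role_catalog import COMPLEMENT_ROLES, RoleAssignment, is_full_transducer

TOLPAL_STATUS_ORDER = {"absent": 0, "partial": 1, "split": 2, "complete": 3}


@dataclass(frozen=True)
class Locus:
    """A proximity cluster of role-bearing genes on one replicon."""

    locus_id: str
    genome_id: str
    replicon_id: str
    genes: tuple[tuple[GeneRecord, RoleAssignment], ...]
    span: tuple[int, int]
    roles_present: tuple[str, ...]  # multiset, sorted

    @property
    def role_set(self) -> frozenset[str]:
        return frozenset(self.roles_present)

    @property
    def organization(self) -> str:
        return "-".join(r.role for _, r in self.genes)


@dataclass
class SystemCall:
    """Per-genome classification of the Tol-Pal and Ton systems."""

    genome_id: str
    tolpal_status: str = "absent"      # complete | split | partial | absent
    ton_status: str = "absent"         # complete | incomplete | absent
    tolA_gene_ids: list[str] = field(default_factory=list)
    tonB_gene_ids: list[str] = field(default_factory=list)
    representative_tonB: Optional[str] = None
    contributing_loci: list[str] = field(default_factory=list)
    cpoB_present: bool = False
    cpoB_adjacent: bool = False
    tolA_ambiguous: bool = False


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def proximity_predicate(
    a: GeneRecord,
    b: GeneRecord,
    max_intervening: int,
    max_gap_bp: int,
    circular: bool = False,
    replicon_n_genes: Optional[int] = None,
    replicon_length: Optional[int] = None,
) -> bool:
    """True when two genes may share a locus (strand-agnostic, symmetric)."""
    if a.replicon_id != b.replicon_id:
        return False
    d = abs(a.rank - b.rank)
    first, second = (a, b) if a.start <= b.start else (b, a)
    gap = max(0, second.start - first.end - 1)
    if circular and replicon_n_genes:
        d = min(d, replicon_n_genes - d)
        if replicon_length:
            wrap_gap = max(0, replicon_length - second.end + first.start - 1)
            gap = min(gap, wrap_gap)
    return d <= max_intervening + 1 and gap <= max_gap_bp


def cluster_loci(
    genes: Sequence[GeneRecord],
    roles: Sequence[RoleAssignment],
    max_intervening: int = 3,
    max_gap_bp: int = 5000,
    circular: bool = False,
    replicon_lengths: Optional[dict[str, int]] = None,
) -> list[Locus]:
    """Connected components of the proximity relation over role-bearing genes.

    Output loci are sorted by (replicon, start); genes within a locus by
    start coordinate.
    """
    if max_intervening < 0:
        raise ValidationError("max_intervening must be >= 0")
    if max_gap_bp <= 0:
        raise ValidationError("max_gap_bp must be > 0")
    gene_by_id = {g.gene_id: g for g in genes}
    role_by_id: dict[str, RoleAssignment] = {}
    for r in roles:
        if r.gene_id not in gene_by_id:
            raise ValidationError(f"role for unknown gene_id {r.gene_id!r}")
        role_by_id[r.gene_id] = r

    bearing = [g for g in genes if role_by_id.get(g.gene_id, None) is not None
               and role_by_id[g.gene_id].role != "none"]
    n_per_replicon = Counter(g.replicon_id for g in genes)
    replicon_lengths = replicon_lengths or {}

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in bearing)
    by_replicon: dict[str, list[GeneRecord]] = {}
    for g in bearing:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for rep, rep_genes in by_replicon.items():
        rep_genes.sort(key=lambda g: g.start)
        for i, a in enumerate(rep_genes):
            for b in rep_genes[i + 1:]:
                if proximity_predicate(
                    a, b, max_intervening, max_gap_bp, circular,
                    n_per_replicon[rep], replicon_lengths.get(rep),
                ):
                    graph.add_edge(a.gene_id, b.gene_id)
                elif not circular and b.start - a.end - 1 > max_gap_bp \
                        and b.rank - a.rank > max_intervening + 1:
                    break  # later genes are even farther on a linear replicon

    loci: list[Locus] = []
    for comp in nx.connected_components(graph):
        members = sorted((gene_by_id[g] for g in comp), key=lambda g: g.start)
        genome_id = members[0].genome_id
        rep = members[0].replicon_id
        pairs = tuple((g, role_by_id[g.gene_id]) for g in members)
        loci.append(Locus(
            locus_id="",  # assigned after global sort
            genome_id=genome_id,
            replicon_id=rep,
            genes=pairs,
            span=(members[0].start, max(g.end for g in members)),
            roles_present=tuple(sorted(role_by_id[g.gene_id].role for g in members)),
        ))
    loci.sort(key=lambda l: (l.replicon_id, l.span[0]))
    return [
        Locus(
            locus_id=f"{l.genome_id}:{l.replicon_id}:{i}",
            genome_id=l.genome_id, replicon_id=l.replicon_id,
            genes=l.genes, span=l.span, roles_present=l.roles_present,
        )
        for i, l in enumerate(loci)
    ]


# ---------------------------------------------------------------------------
# Tol-Pal classification
# ---------------------------------------------------------------------------

def _complement_roles_of(locus: Locus) -> frozenset[str]:
    return locus.role_set & COMPLEMENT_ROLES


def classify_tolpal(loci: Sequence[Locus]) -> tuple[str, list[str]]:
    """Classify one genome's tol-pal status from its loci.

    complete: one locus carries the full minimal complement.
    split:    only a union of >=2 loci does (each contributing >=1 role).
    partial:  some but not all complement roles exist genome-wide.
    absent:   no complement role anywhere.
    Returns (status, contributing locus_ids).
    """
    complete_loci = [l for l in loci if COMPLEMENT_ROLES <= l.role_set]
    if complete_loci:
        # deterministic pick: most complement roles, then lowest start
        best = sorted(
            complete_loci,
            key=lambda l: (-len(_complement_roles_of(l)), l.replicon_id, l.span[0]),
        )[0]
        return "complete", [best.locus_id]
    genome_roles = frozenset().union(*(l.role_set for l in loci)) if loci else frozenset()
    if COMPLEMENT_ROLES <= genome_roles:
        contributing = [l.locus_id for l in loci if _complement_roles_of(l)]
        return "split", contributing
    if genome_roles & COMPLEMENT_ROLES:
        return "partial", []
    return "absent", []


def classify_ton(
    roles: Sequence[RoleAssignment],
    tolA_gene_ids: Sequence[str] = (),
) -> str:
    """Classify the Ton system genome-wide; no proximity requirement.

    complete: a transducer not claimed as TolA, a TBDT, and the motor pair
    all present anywhere on the genome; incomplete: a nonempty proper subset
    of those three; absent otherwise.
    """
    claimed = set(tolA_gene_ids)
    has_transducer = any(
        r.role == "transducer" and r.gene_id not in claimed for r in roles
    )
    has_tbdt = any(r.role == "tbdt" for r in roles)
    has_motor_pair = (
        any(r.role == "motor_pentamer" for r in roles)
        and any(r.role == "motor_dimer" for r in roles)
    )
    n = sum([has_transducer, has_tbdt, has_motor_pair])
    if n == 3:
        return "complete"
    if n >= 1:
        return "incomplete"
    return "absent"


# ---------------------------------------------------------------------------
# Transducer identity
# ---------------------------------------------------------------------------

def assign_transducer_identity(
    tolpal_status: str,
    contributing_loci: Sequence[Locus],
    roles: Sequence[RoleAssignment],
    genes: Sequence[GeneRecord],
) -> tuple[list[str], list[str], bool]:
    """Split transducers into TolA and TonB candidates by genomic context.

    A transducer inside the complement-satisfying locus (or the
    transducer-containing member of a split union) is TolA; at most one TolA
    per genome is kept — if a complete locus holds several transducers the
    call is flagged ambiguous and the one closest in rank to tolB (tie:
    lowest start) wins.  Every other transducer is a TonB candidate, sorted
    by (replicon, start).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    transducers = sorted(
        (r.gene_id for r in roles if r.role == "transducer"),
        key=lambda gid: (gene_by_id[gid].replicon_id, gene_by_id[gid].start),
    )
    tolA: list[str] = []
    ambiguous = False
    if tolpal_status in ("complete", "split"):
        in_complement: list[str] = []
        tolB_ranks: dict[str, list[int]] = {}
        for locus in contributing_loci:
            for g, r in locus.genes:
                if r.role == "transducer":
                    in_complement.append(g.gene_id)
                if r.role == "tolB":
                    tolB_ranks.setdefault(g.replicon_id, []).append(g.rank)
        if len(in_complement) > 1:
            ambiguous = True

            def key(gid: str) -> tuple:
                g = gene_by_id[gid]
                near = tolB_ranks.get(g.replicon_id, [])
                dist = min((abs(g.rank - t) for t in near), default=10 ** 9)
                return (dist, g.replicon_id, g.start)

            in_complement.sort(key=key)
        if in_complement:
            tolA = [in_complement[0]]
    tonB = [gid for gid in transducers if gid not in tolA]
    return tolA, tonB, ambiguous


def select_representative_tonb(
    tonB_gene_ids: Sequence[str],
    genes: Sequence[GeneRecord],
    profiles: dict[str, SecondaryStructureProfile],
) -> Optional[str]:
    """First TonB candidate (by replicon, then start) with all three domains."""
    gene_by_id = {g.gene_id: g for g in genes}
    ordered = sorted(
        tonB_gene_ids,
        key=lambda gid: (gene_by_id[gid].replicon_id, gene_by_id[gid].start),
    )
    for gid in ordered:
        profile = profiles.get(gid)
        length = gene_by_id[gid].protein_length or (
            len(profile) if profile else None
        )
        if profile is not None and is_full_transducer(profile, length):
            return gid
    return None


# ---------------------------------------------------------------------------
# CpoB adjacency
# ---------------------------------------------------------------------------

def cpob_adjacency(
    genes: Sequence[GeneRecord],
    roles: Sequence[RoleAssignment],
    adjacency_rank: int = 1,
) -> tuple[bool, bool]:
    """(cpoB present genome-wide, cpoB within adjacency_rank of a complement gene)."""
    role_by_id = {r.gene_id: r.role for r in roles}
    cpob = [g for g in genes if role_by_id.get(g.gene_id) == "cpoB_tpr"]
    if not cpob:
        return False, False
    complement_genes = [
        g for g in genes if role_by_id.get(g.gene_id) in COMPLEMENT_ROLES
    ]
    for c in cpob:
        for g in complement_genes:
            if g.replicon_id == c.replicon_id and abs(g.rank - c.rank) <= adjacency_rank:
                return True, True
    return True, False


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_genome(
    genes: Sequence[GeneRecord],
    roles: Sequence[RoleAssignment],
    config: RunConfig = RunConfig(),
    profiles: Optional[dict[str, SecondaryStructureProfile]] = None,
    replicon_lengths: Optional[dict[str, int]] = None,
) -> tuple[SystemCall, list[Locus]]:
    """Full per-genome classification: loci, tol-pal/Ton status, identities."""
    genome_id = genes[0].genome_id if genes else "genome"
    loci = cluster_loci(
        genes, roles, config.max_intervening, config.max_gap_bp,
        circular=config.circular, replicon_lengths=replicon_lengths,
    )
    status, contributing_ids = classify_tolpal(loci)
    contributing = [l for l in loci if l.locus_id in contributing_ids]
    tolA, tonB, ambiguous = assign_transducer_identity(
        status, contributing, roles, genes
    )
    ton_status = classify_ton(roles, tolA)
    present, adjacent = (False, False)
    if status in ("complete", "split"):
        present, adjacent = cpob_adjacency(genes, roles, config.adjacency_rank)
    else:
        present = any(r.role == "cpoB_tpr" for r in roles)
    rep_tonb = None
    if profiles is not None and tonB:
        rep_tonb = select_representative_tonb(tonB, genes, profiles)
    return SystemCall(
        genome_id=genome_id,
        tolpal_status=status,
        ton_status=ton_status,
        tolA_gene_ids=tolA,
        tonB_gene_ids=tonB,
        representative_tonB=rep_tonb,
        contributing_loci=contributing_ids,
        cpoB_present=present,
        cpoB_adjacent=adjacent,
        tolA_ambiguous=ambiguous,
    ), loci
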