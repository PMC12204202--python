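"""Synthetic annotated genomes, secondary-structure profiles and cohorts
with planted ground truth.

The generator emulates the curated inputs of the study at zero noise:
genomes carry contiguous planted gene clusters (complete, split, partial,
Ton-only or none) among decoy genes, with the correct Pfam accessions
attached to every planted gene; profiles carry a TMH, an exact number of
helical states and prolines in domain II, and optionally a planted motor
box; cohorts draw species-level domain II lengths from distributions whose
defaults match the observed study cohort (TolA II median 192 residues,
range 110-335; TonB II median 113, range 40-245; weak positive length
correlation rho = 0.28 across species; 70 species).

Everything is deterministic given (spec, seed): identical inputs give
byte-identical outputs.  Placement of helices and prolines is count-exact,
not probabilistic, so composition assertions downstream need no tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    DomainHit,
    GeneRecord,
    SecondaryStructureProfile,
    write_domain_hits,
)
from .role_catalog import COMPLEMENT_ROLES


class SpecError(ValueError):
    """Infeasible or inconsistent generator specification."""


# ---------------------------------------------------------------------------
# Gene-token vocabulary
# ---------------------------------------------------------------------------

#: organization-string token -> (role, Pfam accessions planted)
TOKEN_TABLE: dict[str, tuple[str, tuple[str, ...]]] = {
    "ybgC": ("ybgC", ("PF03061",)),
    "tolQ": ("motor_pentamer", ("PF01618",)),
    "exbB": ("motor_pentamer", ("PF01618",)),
    "tolR": ("motor_dimer", ("PF02472",)),
    "exbD": ("motor_dimer", ("PF02472",)),
    "tolA": ("transducer", ("PF06519", "PF03544")),
    "tonB": ("transducer", ("PF16031", "PF03544")),
    "tolB": ("tolB", ("PF07676", "PF04052")),
    "pal": ("pal", ("PF00691",)),
    "cpoB": ("cpoB_tpr", ("PF16331",)),
    "tbdt": ("tbdt", ("PF00593", "PF07715")),
}

DEFAULT_ORGANIZATION = {
    "complete_tolpal": "ybgC-tolQ-tolR-tolA-tolB-pal-cpoB",
    "split_tolpal": "tolQ-tolR-tolA-tolB // pal-cpoB",
    "ton_only": "exbB-exbD // tonB // tbdt",
    "partial": "tolQ-tolR-tolB",
    "none": "",
}

KINDS = tuple(DEFAULT_ORGANIZATION)


@dataclass(frozen=True)
class PlantedSystem:
    kind: str
    organization: Optional[str] = None  # "//" separates distal clusters

    def clusters(self) -> list[list[str]]:
        org = self.organization
        if org is None:
            org = DEFAULT_ORGANIZATION[self.kind]
        if not org:
            return []
        out = []
        for part in org.split("//"):
            tokens = [t for t in part.strip().split("-") if t]
            for t in tokens:
                if t not in TOKEN_TABLE:
                    raise SpecError(f"unknown organization token {t!r}")
            if tokens:
                out.append(tokens)
        return out


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str = "synthetic"
    n_decoy_genes: int = 40
    replicons: tuple[int, ...] = (2_000_000,)
    planted_systems: tuple[PlantedSystem, ...] = (PlantedSystem("complete_tolpal"),)
    gap_bp_range: tuple[int, int] = (20, 200)
    gene_aa_range: tuple[int, int] = (150, 450)
    split_offset: int = 10  # decoy genes inserted between distal clusters
    decoy_hit_fraction: float = 0.2  # decoys given an off-catalog Pfam hit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoy_genes < 0:
            raise SpecError("n_decoy_genes must be >= 0")
        if self.split_offset < 1:
            raise SpecError("split_offset must be >= 1")
        for s in self.planted_systems:
            if s.kind not in KINDS:
                raise SpecError(f"unknown planted kind {s.kind!r}")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _planted_truth(
    spec: GenomeSpec, cluster_tokens: list[list[str]], gene_ids: dict[int, list[str]]
) -> dict:
    """Intended SystemCall labels, derived from the planted structure alone.

    ``gene_ids`` maps cluster index -> gene ids in organization order.
    """
    roles_per_cluster = [
        [TOKEN_TABLE[t][0] for t in toks] for toks in cluster_tokens
    ]
    genome_roles = set(r for roles in roles_per_cluster for r in roles)

    complete_idx = [
        i for i, roles in enumerate(roles_per_cluster)
        if COMPLEMENT_ROLES <= set(roles)
    ]
    if complete_idx:
        tolpal = "complete"
    elif COMPLEMENT_ROLES <= genome_roles:
        tolpal = "split"
    elif genome_roles & COMPLEMENT_ROLES:
        tolpal = "partial"
    else:
        tolpal = "absent"

    # the transducer inside the complement-satisfying cluster/union is TolA
    tolA: list[str] = []
    if tolpal == "complete":
        i = complete_idx[0]
        for tok, gid in zip(cluster_tokens[i], gene_ids[i]):
            if TOKEN_TABLE[tok][0] == "transducer":
                tolA.append(gid)
                break
    elif tolpal == "split":
        contributing = [
            i for i, roles in enumerate(roles_per_cluster)
            if set(roles) & COMPLEMENT_ROLES
        ]
        for i in contributing:
            for tok, gid in zip(cluster_tokens[i], gene_ids[i]):
                if TOKEN_TABLE[tok][0] == "transducer":
                    tolA.append(gid)
        tolA = tolA[:1]
    tonB = [
        gid
        for i, toks in enumerate(cluster_tokens)
        for tok, gid in zip(toks, gene_ids[i])
        if TOKEN_TABLE[tok][0] == "transducer" and gid not in tolA
    ]

    has_free_transducer = bool(tonB)
    has_tbdt = "tbdt" in genome_roles
    has_motor_pair = {"motor_pentamer", "motor_dimer"} <= genome_roles
    n = sum([has_free_transducer, has_tbdt, has_motor_pair])
    ton = "complete" if n == 3 else ("incomplete" if n >= 1 else "absent")

    cpob_present = "cpoB_tpr" in genome_roles
    cpob_adjacent = False
    for toks in cluster_tokens:
        roles = [TOKEN_TABLE[t][0] for t in toks]
        for i, r in enumerate(roles):
            if r != "cpoB_tpr":
                continue
            neighbors = roles[max(0, i - 1):i] + roles[i + 1:i + 2]
            if any(x in COMPLEMENT_ROLES for x in neighbors):
                cpob_adjacent = True
    return {
        "genome_id": spec.genome_id,
        "tolpal_status": tolpal,
        "ton_status": ton,
        "tolA_gene_ids": tolA,
        "tonB_gene_ids": tonB,
        "cpoB_present": cpob_present,
        "cpoB_adjacent": cpob_adjacent,
    }


def generate_genome(
    spec: GenomeSpec,
) -> tuple[list[GeneRecord], list[DomainHit], dict]:
    """Plant the spec's systems among decoys on replicon coordinates.

    Returns (gene table, domain-hit table, truth labels).  Planted genes get
    their catalog Pfam accessions at E-value 1e-30; decoys get either no hit
    or an off-catalog accession.  Distal planted clusters are separated by
    ``split_offset`` decoy genes, so they never satisfy the rank predicate
    at its default width.
    """
    rng = np.random.default_rng(spec.seed)
    clusters: list[list[str]] = []
    for system in spec.planted_systems:
        clusters.extend(system.clusters())

    # slot layout: decoys before / between (split_offset) / after clusters
    n_between = spec.split_offset * max(0, len(clusters) - 1)
    n_free = spec.n_decoy_genes - n_between
    if n_free < 0:
        raise SpecError(
            f"n_decoy_genes={spec.n_decoy_genes} cannot buffer {len(clusters)} "
            f"clusters at split_offset={spec.split_offset}"
        )
    n_before = int(rng.integers(0, n_free + 1))
    n_after = n_free - n_before

    slots: list[Optional[tuple[int, str]]] = []  # (cluster idx, token) or decoy
    slots.extend([None] * n_before)
    for ci, toks in enumerate(clusters):
        if ci > 0:
            slots.extend([None] * spec.split_offset)
        slots.extend((ci, t) for t in toks)
    slots.extend([None] * n_after)

    replicon_id = "rep1"
    replicon_len = spec.replicons[0]
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    gene_ids_per_cluster: dict[int, list[str]] = {i: [] for i in range(len(clusters))}
    pos = 1
    lo_gap, hi_gap = spec.gap_bp_range
    lo_aa, hi_aa = spec.gene_aa_range
    for idx, slot in enumerate(slots):
        gap = int(rng.integers(lo_gap, hi_gap + 1))
        aa = int(rng.integers(lo_aa, hi_aa + 1))
        start = pos + gap
        end = start + 3 * aa - 1
        if end > replicon_len:
            raise SpecError(
                f"genes exceed replicon length {replicon_len} at slot {idx}"
            )
        gid = f"{spec.genome_id}_g{idx:04d}"
        strand = "+" if rng.random() < 0.7 else "-"
        if slot is None:
            product = "hypothetical protein"
            if rng.random() < spec.decoy_hit_fraction:
                fake = f"PF9{int(rng.integers(0, 10_000)):04d}"
                hits.append(DomainHit(
                    gene_id=gid, pfam_acc=fake, bitscore=float(rng.integers(20, 60)),
                    evalue=10.0 ** float(-rng.integers(6, 30)),
                    env_start=5, env_end=min(aa, 120),
                ))
        else:
            ci, token = slot
            product = f"{token} protein"
            gene_ids_per_cluster[ci].append(gid)
            role, accessions = TOKEN_TABLE[token]
            for k, acc in enumerate(accessions):
                hits.append(DomainHit(
                    gene_id=gid, pfam_acc=acc,
                    bitscore=150.0 - 10.0 * k, evalue=1e-30,
                    env_start=1 + 30 * k, env_end=min(aa, 100 + 30 * k),
                ))
        genes.append(GeneRecord(
            gene_id=gid, genome_id=spec.genome_id, replicon_id=replicon_id,
            start=start, end=end, strand=strand, rank=idx, product=product,
            protein_length=aa,
        ))
        pos = end
    truth = _planted_truth(spec, clusters, gene_ids_per_cluster)
    return genes, hits, truth


def generate_scatter_genome(
    n_genes: int,
    seed: int,
    role_density: float = 0.4,
    genome_id: str = "scatter",
    gap_bp_range: tuple[int, int] = (0, 8000),
) -> tuple[list[GeneRecord], list[DomainHit]]:
    """Random scatter of role-bearing genes among decoys (no planted truth).

    Intergenic gaps straddle the default 5 kb locus threshold, so clustering
    outcomes are nontrivial; intended for oracle and monotonicity checks.
    """
    rng = np.random.default_rng(seed)
    tokens = list(TOKEN_TABLE)
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    pos = 1
    for idx in range(n_genes):
        gap = int(rng.integers(gap_bp_range[0], gap_bp_range[1] + 1))
        aa = int(rng.integers(120, 400))
        start = pos + gap + 1
        end = start + 3 * aa - 1
        gid = f"{genome_id}_g{idx:04d}"
        if rng.random() < role_density:
            token = tokens[int(rng.integers(0, len(tokens)))]
            for k, acc in enumerate(TOKEN_TABLE[token][1]):
                hits.append(DomainHit(
                    gene_id=gid, pfam_acc=acc, bitscore=120.0 - 5 * k,
                    evalue=1e-20, env_start=1 + 20 * k,
                    env_end=min(aa, 90 + 20 * k),
                ))
        genes.append(GeneRecord(
            gene_id=gid, genome_id=genome_id, replicon_id="rep1",
            start=start, end=end, strand="+" if rng.random() < 0.5 else "-",
            rank=idx, product="protein", protein_length=aa,
        ))
        pos = end
    return genes, hits


# ---------------------------------------------------------------------------
# Profile generation
# ---------------------------------------------------------------------------

_SEQ_ALPHABET = np.array(list("ADEFGHIKLMNQRSTVWY"))  # no P, no C


@dataclass(frozen=True)
class ProfileSpec:
    gene_id: str = "protein"
    protein_length: int = 300
    tmh_span: Optional[tuple[int, int]] = (10, 30)
    target_helix_count: int = 60
    target_proline_count: int = 20
    motor_box: bool = True
    motor_box_window: int = 75
    min_strand: int = 3
    min_coil_flank: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tmh_span is not None:
            s, e = self.tmh_span
            if not (1 <= s <= e <= self.protein_length):
                raise SpecError(f"TMH span {self.tmh_span} infeasible")
        if self.target_helix_count < 0 or self.target_proline_count < 0:
            raise SpecError("target counts must be >= 0")


def _domain2_bounds(spec: ProfileSpec) -> tuple[int, int]:
    if spec.tmh_span is None:
        raise SpecError("profile spec without TMH has no domain II")
    d2_start = spec.tmh_span[1] + 1
    d2_end = spec.protein_length - 100
    if d2_start > d2_end:
        raise SpecError("protein too short for a non-empty domain II")
    return d2_start, d2_end


def generate_profile(
    spec: ProfileSpec,
) -> tuple[SecondaryStructureProfile, str]:
    """Count-exact profile + sequence for one transducer.

    Domain II receives exactly ``target_helix_count`` H states and exactly
    ``target_proline_count`` prolines at seed-randomized positions.  When
    ``motor_box`` is set, a strand of ``min_strand + 1`` E states with
    ``min_coil_flank`` coil residues on each side is planted so that it
    begins inside the detection window; otherwise no E state appears in the
    protein at all.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.protein_length
    states = np.full(L, "C")
    if spec.tmh_span is not None:
        states[spec.tmh_span[0] - 1:spec.tmh_span[1]] = "H"
        d2_start, d2_end = _domain2_bounds(spec)
        d2_idx = np.arange(d2_start - 1, d2_end)  # 0-based
        reserved = np.zeros(L, dtype=bool)
        if spec.motor_box:
            run_len = spec.min_strand + 1
            flank = spec.min_coil_flank
            earliest = flank  # keep the left flank inside domain II
            latest = min(spec.motor_box_window - run_len,
                         (d2_end - d2_start + 1) - run_len - flank)
            if latest < earliest:
                raise SpecError("domain II too short for the requested motor box")
            offset = int(rng.integers(earliest, latest + 1))
            box_start = d2_start + offset  # 1-based
            states[box_start - 1:box_start - 1 + run_len] = "E"
            reserved[box_start - 1 - flank:box_start - 1 + run_len + flank] = True
        free = [i for i in d2_idx if not reserved[i]]
        if spec.target_helix_count > len(free):
            raise SpecError(
                f"target_helix_count={spec.target_helix_count} exceeds "
                f"{len(free)} free domain II residues"
            )
        h_pos = rng.choice(np.array(free), size=spec.target_helix_count, replace=False)
        states[h_pos] = "H"
        d2_len = d2_end - d2_start + 1
        if spec.target_proline_count > d2_len:
            raise SpecError("target_proline_count exceeds domain II length")
    seq = rng.choice(_SEQ_ALPHABET, size=L)
    if spec.tmh_span is not None:
        p_pos = rng.choice(d2_idx, size=spec.target_proline_count, replace=False)
        seq[p_pos] = "P"
        # no stray prolines outside domain II: keeps hand counts unambiguous
        outside = np.setdiff1d(np.arange(L), d2_idx)
        stray = np.isin(seq[outside], ["P"])
        seq[outside[stray]] = "A"
        ppii = np.full(L, 0.05)
        ppii[p_pos] = 0.9
    else:
        seq[seq == "P"] = "A"
        ppii = np.full(L, 0.05)
    profile = SecondaryStructureProfile(
        gene_id=spec.gene_id,
        states="".join(states),
        confidence=[0.95] * L,
        tmh_span=spec.tmh_span,
        ppii_scores=[float(x) for x in ppii],
    )
    return profile, "".join(seq)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

PROTEOBACTERIAL_CLASSES = (
    "Gammaproteobacteria", "Betaproteobacteria", "Alphaproteobacteria",
    "Deltaproteobacteria", "Epsilonproteobacteria", "Acidithiobacillia",
    "Oligoflexia",
)

#: defaults emulate the curated study cohort (domain II length medians and
#: observed ranges per transducer class)
DEFAULT_LENGTH_DISTRIBUTIONS = {
    "TolA": ("lognormal", {"median": 192.0, "sigma": 0.22, "lo": 110, "hi": 335}),
    "TonB": ("lognormal", {"median": 113.0, "sigma": 0.30, "lo": 40, "hi": 245}),
}


def _draw_lengths(family: str, params: dict, z: np.ndarray) -> np.ndarray:
    """Transform standard-normal draws into lengths under the named family."""
    if family == "lognormal":
        vals = params["median"] * np.exp(params["sigma"] * z)
        lo = params.get("lo")
        hi = params.get("hi")
        if lo is not None:
            vals = np.clip(vals, lo, hi)
        return vals
    if family == "normal":
        return params["mean"] + params["sd"] * z
    if family == "uniform":
        from scipy.stats import norm

        u = norm.cdf(z)
        return params["lo"] + (params["hi"] - params["lo"]) * u
    if family == "constant":
        return np.full_like(z, float(params["value"]))
    raise SpecError(f"unknown distribution family {family!r}")


def generate_cohort(
    n_species: int = 70,
    length_distributions: Optional[dict] = None,
    rho: float = 0.28,
    lipo_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Species-level cohort: one TolA and one TonB record per species.

    Paired domain II lengths are drawn through a Gaussian copula with
    correlation ``rho``; composition percentages are drawn per class (TolA
    helix-biased, TonB proline-biased).  Returns (records DataFrame, truth
    parameters).
    """
    if n_species < 1:
        raise SpecError("n_species must be >= 1")
    if not (-1.0 <= rho <= 1.0):
        raise SpecError("rho must be in [-1, 1]")
    dists = length_distributions or DEFAULT_LENGTH_DISTRIBUTIONS
    for cls in ("TolA", "TonB"):
        if cls not in dists:
            raise SpecError(f"missing length distribution for {cls}")
        family = dists[cls][0]
        if family not in ("lognormal", "normal", "uniform", "constant"):
            raise SpecError(f"unknown distribution family {family!r}")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_species)
    tolA_len = np.rint(_draw_lengths(dists["TolA"][0], dists["TolA"][1], z[:, 0]))
    tonB_len = np.rint(_draw_lengths(dists["TonB"][0], dists["TonB"][1], z[:, 1]))

    rows = []
    for i in range(n_species):
        species = f"species_{i:03d}"
        clade = PROTEOBACTERIAL_CLASSES[i % len(PROTEOBACTERIAL_CLASSES)]
        helix_a = float(np.clip(rng.normal(40, 18), 0, 95))
        pro_a = float(np.clip(rng.normal(8, 5), 0, 30))
        helix_b = float(np.clip(rng.normal(10, 7), 0, 60))
        pro_b = float(np.clip(rng.normal(22, 8), 0, 60))
        for cls, length, h, p in (
            ("TolA", tolA_len[i], helix_a, pro_a),
            ("TonB", tonB_len[i], helix_b, pro_b),
        ):
            rows.append({
                "species": species,
                "clade": clade,
                "protein_class": cls,
                "d2_length": int(length),
                "helix_pct": round(h, 2),
                "proline_pct": round(p, 2),
                "composition_class": "",
                "lipo_class": "lipoprotein" if rng.random() < lipo_fraction else "none",
            })
    df = pd.DataFrame(rows)
    truth = {
        "rho": rho,
        "n_species": n_species,
        "length_distributions": {k: [v[0], dict(v[1])] for k, v in dists.items()},
        "lipo_fraction": lipo_fraction,
        "seed": seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Fixture-bundle writers (same dialects formats_io reads)
# ---------------------------------------------------------------------------

def write_genome_bundle(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    truth: dict,
    out_dir: str | Path,
    genome_id: Optional[str] = None,
) -> dict[str, Path]:
    """Write a genome as GFF3 + hmmscan domtblout + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_id = genome_id or (genes[0].genome_id if genes else "genome")
    gff = out_dir / f"{genome_id}.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.start)):
            attrs = f"ID={g.gene_id};product={g.product}"
            fh.write(
                f"{g.replicon_id}\ttoltrace_synth\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )
    dom = out_dir / f"{genome_id}.domtblout"
    write_domain_hits(
        hits, dom, protein_lengths={g.gene_id: g.protein_length for g in genes}
    )
    tpath = out_dir / f"{genome_id}.truth.json"
    tpath.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"gff3": gff, "domtblout": dom, "truth": tpath}


def write_profile_bundle(
    profiles: Sequence[SecondaryStructureProfile],
    sequences: dict[str, str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write profiles as per-protein ss2 files + FASTA + TMH/PPII tables."""
    from .formats_io import write_ss2

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "proteins.fasta"
    with open(fasta, "w") as fh:
        for p in profiles:
            seq = sequences[p.gene_id]
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    tmh = out_dir / "tmh_spans.tsv"
    with open(tmh, "w") as fh:
        fh.write("gene_id\ttmh_start\ttmh_end\n")
        for p in profiles:
            if p.tmh_span is not None:
                fh.write(f"{p.gene_id}\t{p.tmh_span[0]}\t{p.tmh_span[1]}\n")
    ppii = out_dir / "ppii_scores.tsv"
    with open(ppii, "w") as fh:
        fh.write("gene_id\tppii_scores\n")
        for p in profiles:
            if p.ppii_scores is not None:
                fh.write(
                    f"{p.gene_id}\t" + ",".join(f"{s:.3f}" for s in p.ppii_scores) + "\n"
                )
    paths = {"fasta": fasta, "tmh": tmh, "ppii": ppii}
    for p in profiles:
        sp = out_dir / f"{p.gene_id}.ss2"
        write_ss2(p, sp, sequences.get(p.gene_id))
        paths[f"ss2:{p.gene_id}"] = sp
    return paths
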