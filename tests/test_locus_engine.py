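"""Locus clustering, tol-pal / Ton classification and transducer identity."""

import pytest

from toltrace.config import RunConfig
from toltrace.formats_io import SecondaryStructureProfile, ValidationError
from toltrace.locus_engine import (
    analyze_genome,
    assign_transducer_identity,
    classify_tolpal,
    classify_ton,
    cluster_loci,
    cpob_adjacency,
    select_representative_tonb,
)
from toltrace.role_catalog import assign_roles
from toltrace.synthetic_data import generate_scatter_genome


def build_operon(make_gene, make_role, roles, replicon="rep1", start=1000,
                 gene_bp=900, gap=100, rank0=0):
    """Consecutive genes with the given roles (None -> decoy)."""
    genes, assignments = [], []
    pos = start
    for i, role in enumerate(roles):
        g = make_gene(f"{replicon}_g{rank0 + i}", pos, pos + gene_bp - 1,
                      replicon=replicon, rank=rank0 + i)
        genes.append(g)
        if role is not None:
            assignments.append(make_role(g.gene_id, role))
        pos += gene_bp + gap
    return genes, assignments


ECOLI_ORDER = ["ybgC", "motor_pentamer", "motor_dimer", "transducer",
               "tolB", "pal", "cpoB_tpr"]


class TestClusterLoci:
    def test_ecoli_style_operon_is_one_locus(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ECOLI_ORDER)
        loci = cluster_loci(genes, roles)
        assert len(loci) == 1
        assert loci[0].organization == "-".join(ECOLI_ORDER)

    def test_genes_on_different_replicons_never_co_cluster(self, make_gene, make_role):
        g1, r1 = build_operon(make_gene, make_role, ["pal"], replicon="chr")
        g2, r2 = build_operon(make_gene, make_role, ["cpoB_tpr"], replicon="plasmid")
        loci = cluster_loci(g1 + g2, r1 + r2)
        assert len(loci) == 2
        assert {l.replicon_id for l in loci} == {"chr", "plasmid"}

    def test_decoy_gap_within_max_intervening_bridges(self, make_gene, make_role):
        genes, roles = build_operon(
            make_gene, make_role, ["transducer", None, None, None, "tolB"]
        )
        assert len(cluster_loci(genes, roles, max_intervening=3)) == 1
        assert len(cluster_loci(genes, roles, max_intervening=2)) == 2

    def test_bp_gap_threshold_splits(self, make_gene, make_role):
        genes, roles = build_operon(
            make_gene, make_role, ["transducer", "tolB"], gap=6000
        )
        assert len(cluster_loci(genes, roles, max_gap_bp=5000)) == 2
        assert len(cluster_loci(genes, roles, max_gap_bp=7000)) == 1

    def test_unknown_gene_id_in_roles_rejected(self, make_gene, make_role):
        genes, _ = build_operon(make_gene, make_role, [None])
        with pytest.raises(ValidationError):
            cluster_loci(genes, [make_role("ghost", "pal")])


def brute_force_components(genes, roles, max_intervening, max_gap_bp):
    """Independent O(n^2) transitive closure of the pairwise predicate."""
    role_by_id = {r.gene_id: r.role for r in roles}
    bearing = [g for g in genes if role_by_id.get(g.gene_id, "none") != "none"]

    def linked(a, b):
        if a.replicon_id != b.replicon_id:
            return False
        lo, hi = (a, b) if a.start <= b.start else (b, a)
        gap = max(0, hi.start - lo.end - 1)
        return abs(a.rank - b.rank) <= max_intervening + 1 and gap <= max_gap_bp

    sets = [{g.gene_id} for g in bearing]
    by_id = {g.gene_id: g for g in bearing}
    changed = True
    while changed:
        changed = False
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] and sets[j] and any(
                    linked(by_id[x], by_id[y]) for x in sets[i] for y in sets[j]
                ):
                    sets[i] |= sets[j]
                    sets[j] = set()
                    changed = True
    return {frozenset(s) for s in sets if s}


@pytest.mark.parametrize("seed", range(0, 20))
def test_clustering_equals_brute_force_closure(seed):
    genes, hits = generate_scatter_genome(n_genes=40, seed=seed)
    roles = assign_roles(hits)
    loci = cluster_loci(genes, roles, max_intervening=3, max_gap_bp=5000)
    got = {frozenset(g.gene_id for g, _ in l.genes) for l in loci}
    expected = brute_force_components(genes, roles, 3, 5000)
    assert got == expected


class TestClassifyTolpal:
    def test_single_complete_locus(self, make_gene, make_role):
        genes, roles = build_operon(
            make_gene, make_role,
            ["motor_pentamer", "motor_dimer", "transducer", "tolB", "pal"],
        )
        status, contributing = classify_tolpal(cluster_loci(genes, roles))
        assert status == "complete"
        assert len(contributing) == 1

    def test_split_across_two_distal_loci(self, make_gene, make_role):
        g1, r1 = build_operon(
            make_gene, make_role,
            ["motor_pentamer", "motor_dimer", "transducer", "tolB"],
        )
        g2, r2 = build_operon(
            make_gene, make_role, ["pal", "cpoB_tpr"], start=500_000, rank0=20
        )
        status, contributing = classify_tolpal(cluster_loci(g1 + g2, r1 + r2))
        assert status == "split"
        assert len(contributing) == 2

    def test_partial_when_some_complement_roles_missing(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["transducer"])
        status, _ = classify_tolpal(cluster_loci(genes, roles))
        assert status == "partial"

    def test_absent_without_complement_roles(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["ybgC", "cpoB_tpr"])
        status, _ = classify_tolpal(cluster_loci(genes, roles))
        assert status == "absent"

    def test_tolb_like_does_not_satisfy_complement(self, make_gene, make_role):
        genes, roles = build_operon(
            make_gene, make_role,
            ["motor_pentamer", "motor_dimer", "transducer", "tolB_like", "pal"],
        )
        status, _ = classify_tolpal(cluster_loci(genes, roles))
        assert status == "partial"


class TestClassifyTon:
    def test_all_three_components_distal_is_complete(self, make_role):
        roles = [make_role("a", "transducer"), make_role("b", "tbdt"),
                 make_role("c", "motor_pentamer"), make_role("d", "motor_dimer")]
        assert classify_ton(roles) == "complete"

    def test_tbdt_only_is_incomplete(self, make_role):
        assert classify_ton([make_role("a", "tbdt")]) == "incomplete"

    def test_no_relevant_roles_is_absent(self, make_role):
        assert classify_ton([make_role("a", "ybgC")]) == "absent"

    def test_transducer_claimed_as_tolA_does_not_count(self, make_role):
        roles = [make_role("a", "transducer"), make_role("b", "tbdt"),
                 make_role("c", "motor_pentamer"), make_role("d", "motor_dimer")]
        assert classify_ton(roles, tolA_gene_ids=["a"]) == "incomplete"


class TestTransducerIdentity:
    def test_transducer_in_complete_locus_is_tolA(self, make_gene, make_role):
        genes, roles = build_operon(
            make_gene, make_role,
            ["motor_pentamer", "motor_dimer", "transducer", "tolB", "pal"],
        )
        loci = cluster_loci(genes, roles)
        status, ids = classify_tolpal(loci)
        contributing = [l for l in loci if l.locus_id in ids]
        tolA, tonB, amb = assign_transducer_identity(status, contributing, roles, genes)
        assert tolA == [genes[2].gene_id]
        assert tonB == []
        assert not amb

    def test_transducer_without_context_is_tonB(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["transducer"])
        loci = cluster_loci(genes, roles)
        status, ids = classify_tolpal(loci)
        tolA, tonB, _ = assign_transducer_identity(status, [], roles, genes)
        assert tolA == []
        assert tonB == [genes[0].gene_id]

    def test_no_transducers_gives_empty_lists(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["pal"])
        tolA, tonB, _ = assign_transducer_identity("partial", [], roles, genes)
        assert tolA == [] and tonB == []

    def test_two_transducers_in_complete_locus_flagged_nearest_tolb_wins(
        self, make_gene, make_role
    ):
        genes, roles = build_operon(
            make_gene, make_role,
            ["transducer", "motor_pentamer", "motor_dimer", "transducer",
             "tolB", "pal"],
        )
        loci = cluster_loci(genes, roles)
        status, ids = classify_tolpal(loci)
        contributing = [l for l in loci if l.locus_id in ids]
        tolA, tonB, amb = assign_transducer_identity(status, contributing, roles, genes)
        assert amb
        assert tolA == [genes[3].gene_id]  # rank distance 1 to tolB
        assert tonB == [genes[0].gene_id]


class TestRepresentativeTonB:
    def _profile(self, gid, length, tmh):
        return SecondaryStructureProfile(
            gene_id=gid, states="C" * length, tmh_span=tmh
        )

    def test_first_full_three_domain_candidate_wins(self, make_gene):
        genes = [make_gene("frag", 1000, 1330, rank=0, protein_length=110),
                 make_gene("full", 5000, 5900, rank=1, protein_length=300)]
        profiles = {"frag": self._profile("frag", 110, (10, 30)),
                    "full": self._profile("full", 300, (10, 30))}
        assert select_representative_tonb(["frag", "full"], genes, profiles) == "full"

    def test_all_candidates_without_tmh_gives_none(self, make_gene):
        genes = [make_gene("a", 1000, 1900, rank=0, protein_length=300)]
        profiles = {"a": self._profile("a", 300, None)}
        assert select_representative_tonb(["a"], genes, profiles) is None

    def test_single_full_candidate_selected(self, make_gene):
        genes = [make_gene("a", 1000, 1900, rank=0, protein_length=300)]
        profiles = {"a": self._profile("a", 300, (5, 25))}
        assert select_representative_tonb(["a"], genes, profiles) == "a"


class TestCpoBAdjacency:
    def test_cpob_immediately_downstream_of_pal(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["pal", "cpoB_tpr"])
        assert cpob_adjacency(genes, roles) == (True, True)

    def test_cpob_on_another_replicon_is_present_not_adjacent(
        self, make_gene, make_role
    ):
        g1, r1 = build_operon(make_gene, make_role, ["pal"], replicon="chr")
        g2, r2 = build_operon(make_gene, make_role, ["cpoB_tpr"], replicon="pl")
        assert cpob_adjacency(g1 + g2, r1 + r2) == (True, False)

    def test_no_cpob(self, make_gene, make_role):
        genes, roles = build_operon(make_gene, make_role, ["pal"])
        assert cpob_adjacency(genes, roles) == (False, False)


STATUS_ORDER = {"absent": 0, "partial": 1, "split": 2, "complete": 3}


@pytest.mark.parametrize("seed", range(5))
def test_widening_thresholds_only_merges_loci_and_promotes_status(seed):
    genes, hits = generate_scatter_genome(n_genes=40, seed=seed)
    roles = assign_roles(hits)
    narrow = cluster_loci(genes, roles, max_intervening=1, max_gap_bp=2000)
    wide = cluster_loci(genes, roles, max_intervening=4, max_gap_bp=8000)
    wide_sets = [set(g.gene_id for g, _ in l.genes) for l in wide]
    for locus in narrow:
        members = set(g.gene_id for g, _ in locus.genes)
        assert any(members <= w for w in wide_sets)
    s_narrow, _ = classify_tolpal(narrow)
    s_wide, _ = classify_tolpal(wide)
    assert STATUS_ORDER[s_wide] >= STATUS_ORDER[s_narrow]


def test_system_call_reproducible_from_inputs_alone(make_gene, make_role):
    genes, roles = build_operon(make_gene, make_role, ECOLI_ORDER)
    call1, _ = analyze_genome(genes, roles, RunConfig())
    call2, _ = analyze_genome(list(reversed(genes)), list(reversed(roles)), RunConfig())
    assert call1 == call2
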