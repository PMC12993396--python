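"""Ontology: loading, information content, matching, similarity, branches."""

import math

import numpy as np
import pytest

from pgr.ontology import (
    AnnotationCorpus,
    OntologyError,
    combine_profiles,
    information_content,
    load_obo,
    match_features,
    prune_branch,
    similarity,
    third_level_partition,
)


def _write_obo(path, stanzas):
    lines = ["format-version: 1.2", ""]
    for tid, parents, obsolete in stanzas:
        lines += ["[Term]", f"id: {tid}", f"name: {tid}"]
        lines += [f"is_a: {p}" for p in parents]
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def test_linear_chain_loads_with_root_and_levels(tmp_path):
    ids = [f"HP:000000{i}" for i in range(1, 6)]
    onto = load_obo(
        _write_obo(tmp_path / "chain.obo", [(t, [ids[i - 1]] if i else [], False) for i, t in enumerate(ids)])
    )
    assert onto.root == ids[0]
    assert [onto.level(t) for t in ids] == [1, 2, 3, 4, 5]


def test_cycle_raises(tmp_path):
    path = _write_obo(
        tmp_path / "cycle.obo",
        [("HP:0000001", ["HP:0000002"], False), ("HP:0000002", ["HP:0000001"], False)],
    )
    with pytest.raises(OntologyError, match="cycle"):
        load_obo(path)


def test_multiple_roots_raise(tmp_path):
    path = _write_obo(
        tmp_path / "two.obo", [("HP:0000001", [], False), ("HP:0000002", [], False)]
    )
    with pytest.raises(OntologyError, match="root"):
        load_obo(path)


def test_diamond_keeps_both_parent_paths(tiny_ontology):
    assert tiny_ontology.parents["HP:0000007"] == {"HP:0000004", "HP:0000006"}
    anc = tiny_ontology.ancestors_or_self("HP:0000007")
    assert {"HP:0000002", "HP:0000003"} <= anc  # reachable through both sides


@pytest.fixture()
def eight_gene_corpus(tiny_ontology):
    # 8 genes; root is an ancestor of every annotation after propagation.
    terms = ["HP:0000004", "HP:0000004", "HP:0000005", "HP:0000006",
             "HP:0000007", "HP:0000008", "HP:0000009", "HP:0000009"]
    return AnnotationCorpus({f"G{i}": frozenset([t]) for i, t in enumerate(terms)})


def test_information_content_hand_values(tiny_ontology, eight_gene_corpus):
    ic = information_content(tiny_ontology, eight_gene_corpus)
    assert ic[tiny_ontology.root] == 0.0
    # HP:0000005 annotates exactly 1 of 8 genes
    assert ic["HP:0000005"] == pytest.approx(-math.log(1 / 8))
    assert ic["HP:0000005"] >= 2.0  # clears the IC cutoff of two
    # HP:0000009 annotates 2 of 8 -> ln 4
    assert ic["HP:0000009"] == pytest.approx(math.log(4))


def test_information_content_empty_corpus_raises(tiny_ontology):
    with pytest.raises(OntologyError):
        information_content(tiny_ontology, AnnotationCorpus({}))


def test_information_content_matches_bruteforce(tiny_ontology, eight_gene_corpus):
    ic = information_content(tiny_ontology, eight_gene_corpus)
    genes = eight_gene_corpus.gene_terms
    for term in tiny_ontology.parents:
        n = sum(
            1
            for terms in genes.values()
            if any(term in tiny_ontology.ancestors_or_self(t) for t in terms)
        )
        expected = -math.log(n / len(genes)) if n else math.inf
        assert ic[term] == pytest.approx(expected)


@pytest.mark.parametrize(
    "patient,gene,exact,one_level",
    [
        ({"HP:0000004"}, {"HP:0000004"}, 1, 0),            # identity
        ({"HP:0000008"}, {"HP:0000004"}, 0, 1),            # child of gene term
        ({"HP:0000004"}, {"HP:0000008"}, 0, 1),            # parent of gene term
        ({"HP:0000009"}, {"HP:0000004"}, 0, 0),            # two levels apart
        ({"HP:0000004"}, {"HP:0000005"}, 0, 0),            # siblings excluded
    ],
)
def test_match_features_counts(tiny_ontology, eight_gene_corpus, patient, gene, exact, one_level):
    ic = information_content(tiny_ontology, eight_gene_corpus)
    m = match_features(patient, gene, tiny_ontology, ic)
    assert (m.exact_count, m.one_level_count) == (exact, one_level)


def test_match_features_ic_cutoffs_apply_to_exact_matches(tiny_ontology, eight_gene_corpus):
    ic = information_content(tiny_ontology, eight_gene_corpus)
    m = match_features({"HP:0000005"}, {"HP:0000005"}, tiny_ontology, ic)
    assert m.exact_count == 1 and m.ic2_count == 1 and m.ic4_count == 0


def test_match_features_unknown_term_raises(tiny_ontology, eight_gene_corpus):
    ic = information_content(tiny_ontology, eight_gene_corpus)
    with pytest.raises(OntologyError, match="HP:9999999"):
        match_features({"HP:9999999"}, {"HP:0000004"}, tiny_ontology, ic)


class TestSimilarity:
    def test_identical_singletons_score_their_ic(self, tiny_ontology, eight_gene_corpus):
        ic = information_content(tiny_ontology, eight_gene_corpus)
        t = "HP:0000005"
        assert similarity({t}, {t}, tiny_ontology, ic) == pytest.approx(ic[t])

    def test_sets_sharing_only_root_score_zero(self, tiny_ontology, eight_gene_corpus):
        ic = information_content(tiny_ontology, eight_gene_corpus)
        # HP:0000005 (under A) vs HP:0000006 (under B): MICA is the root
        assert similarity({"HP:0000005"}, {"HP:0000006"}, tiny_ontology, ic) == 0.0

    def test_empty_gene_set_scores_zero(self, tiny_ontology, eight_gene_corpus):
        ic = information_content(tiny_ontology, eight_gene_corpus)
        assert similarity({"HP:0000004"}, set(), tiny_ontology, ic) == 0.0

    def test_matches_exhaustive_mica_bruteforce(self, tiny_ontology, eight_gene_corpus):
        ic = information_content(tiny_ontology, eight_gene_corpus)

        def mica(a, b):
            common = tiny_ontology.ancestors_or_self(a) & tiny_ontology.ancestors_or_self(b)
            return max((ic[t] for t in common if math.isfinite(ic[t])), default=0.0)

        patient = {"HP:0000004", "HP:0000009"}
        gene = {"HP:0000007"}
        fwd = sum(max(mica(p, g) for g in gene) for p in patient) / len(patient)
        rev = sum(max(mica(g, p) for p in patient) for g in gene) / len(gene)
        assert similarity(patient, gene, tiny_ontology, ic) == pytest.approx((fwd + rev) / 2)

    def test_symmetry_nonnegativity_and_per_term_self_dominance(
        self, tiny_ontology, eight_gene_corpus
    ):
        """Symmetric, nonnegative, and no term matches any other term
        better than itself (the common-ancestor IC is bounded by the
        term's own best finite ancestor IC)."""
        ic = information_content(tiny_ontology, eight_gene_corpus)

        def mica(a, b):
            common = tiny_ontology.ancestors_or_self(a) & tiny_ontology.ancestors_or_self(b)
            return max((ic[t] for t in common if math.isfinite(ic[t])), default=0.0)

        rng = np.random.default_rng(0)
        active = sorted(t for t in tiny_ontology.parents if t not in tiny_ontology.obsolete)
        for _ in range(30):
            s = set(rng.choice(active, size=2, replace=False))
            t = set(rng.choice(active, size=2, replace=False))
            st = similarity(s, t, tiny_ontology, ic)
            assert st == pytest.approx(similarity(t, s, tiny_ontology, ic))
            assert st >= 0.0
            for term in s:
                assert max(mica(term, other) for other in t) <= mica(term, term) + 1e-12


def test_combine_profiles_union_drops_obsolete(tiny_ontology):
    profile = combine_profiles({"HP:0000004"}, {"HP:0000004", "HP:0000005", "HP:0000010"}, tiny_ontology)
    assert profile.combined_terms == {"HP:0000004", "HP:0000005"}
    assert profile.nlp_terms == {"HP:0000004", "HP:0000005"}
    empty_manual = combine_profiles(set(), {"HP:0000006"}, tiny_ontology)
    assert empty_manual.combined_terms == {"HP:0000006"}


class TestBranchPartition:
    def test_groups_by_level3_anchor(self, tiny_ontology):
        # A1 (level 3) anchors itself + A1a + A1a1; B1 anchors itself
        branches = third_level_partition(
            {"HP:0000004", "HP:0000008", "HP:0000006"}, tiny_ontology
        )
        by_anchor = {b.anchor: b.members for b in branches}
        assert by_anchor["HP:0000004"] == {"HP:0000004", "HP:0000008"}
        assert by_anchor["HP:0000006"] == {"HP:0000006"}

    def test_empty_set_yields_no_branches(self, tiny_ontology):
        assert third_level_partition(set(), tiny_ontology) == []

    def test_shallow_terms_fall_in_residual(self, tiny_ontology):
        (residual,) = third_level_partition({"HP:0000002"}, tiny_ontology)
        assert residual.anchor is None and residual.members == {"HP:0000002"}

    def test_diamond_term_joins_both_branches(self, tiny_ontology):
        # HP:0000007 descends from both A1 and B1 (both level 3)
        branches = third_level_partition({"HP:0000007"}, tiny_ontology)
        anchors = {b.anchor for b in branches}
        assert anchors == {"HP:0000004", "HP:0000006"}

    def test_union_of_branches_covers_term_set(self, tiny_ontology):
        rng = np.random.default_rng(1)
        active = sorted(t for t in tiny_ontology.parents if t not in tiny_ontology.obsolete)
        for _ in range(25):
            terms = set(rng.choice(active, size=3, replace=False))
            branches = third_level_partition(terms, tiny_ontology)
            covered = set().union(*(b.members for b in branches))
            assert covered == terms


class TestPruneBranch:
    def test_removes_branch_members(self, tiny_ontology):
        profile = combine_profiles({"HP:0000004", "HP:0000008", "HP:0000006"}, set(), tiny_ontology)
        branch = next(
            b for b in third_level_partition(profile.manual_terms, tiny_ontology)
            if b.anchor == "HP:0000004"
        )
        pruned = prune_branch(profile, branch)
        assert pruned.manual_terms == {"HP:0000006"}

    def test_full_removal_yields_empty_profile(self, tiny_ontology):
        profile = combine_profiles({"HP:0000006"}, set(), tiny_ontology)
        (branch,) = third_level_partition(profile.manual_terms, tiny_ontology)
        assert prune_branch(profile, branch).manual_terms == frozenset()

    def test_foreign_branch_raises(self, tiny_ontology):
        from pgr.ontology import Branch

        profile = combine_profiles({"HP:0000006"}, set(), tiny_ontology)
        with pytest.raises(OntologyError):
            prune_branch(profile, Branch(anchor="HP:0000004", members=frozenset({"HP:0000004"})))

    def test_repartition_never_recreates_pruned_anchor(self, tiny_ontology):
        rng = np.random.default_rng(2)
        active = sorted(t for t in tiny_ontology.parents if t not in tiny_ontology.obsolete)
        for _ in range(50):
            terms = set(rng.choice(active, size=3, replace=False))
            profile = combine_profiles(terms, set(), tiny_ontology)
            for branch in third_level_partition(terms, tiny_ontology):
                if branch.anchor is None:
                    continue
                pruned = prune_branch(profile, branch)
                anchors_after = {
                    b.anchor for b in third_level_partition(pruned.manual_terms, tiny_ontology)
                }
                assert branch.anchor not in anchors_after
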