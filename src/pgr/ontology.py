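"""HPO-style ontology handling.

Loads an OBO flat file into a validated DAG, computes Resnik-style
information content over a gene-annotation corpus, extracts patient/gene
term-match features, scores phenotype similarity (symmetric
best-match-average over most-informative common ancestors), and implements
the third-level branch partition plus branch pruning used by the
phenotype-cluster ablation experiment.

Conventions: information content is in natural-log units, ``ic(root) = 0``,
unannotated terms get ``+inf``.  Depth levels count the root as level 1 and
use the minimum depth for multi-parent terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

from .types import PhenotypeProfile


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class Branch:
    """Patient terms grouped under one third-level ancestor.

    ``anchor`` is ``None`` for the residual branch holding terms shallower
    than level 3.
    """

    anchor: Optional[str]
    members: frozenset[str]


@dataclass
class AnnotationCorpus:
    """Gene-to-term annotations; ``propagated`` means each gene's set is
    closed under ontology ancestors."""

    gene_terms: dict[str, frozenset[str]]
    propagated: bool = False


class Ontology:
    """A rooted DAG of phenotype terms.

    Obsolete terms are retained (so profiles referencing them can be
    cleaned) but take no part in the graph structure.
    """

    def __init__(
        self,
        parents: Mapping[str, frozenset[str]],
        names: Mapping[str, str],
        obsolete: frozenset[str],
    ) -> None:
        self.parents = {t: frozenset(p) for t, p in parents.items()}
        self.names = dict(names)
        self.obsolete = obsolete
        self._validate()
        self.children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)

    def _validate(self) -> None:
        active = [t for t in self.parents if t not in self.obsolete]
        g = nx.DiGraph()
        g.add_nodes_from(active)
        for t in active:
            for p in self.parents[t]:
                if p not in self.parents:
                    raise OntologyError(f"term {t} has unknown parent {p}")
                g.add_edge(t, p)
        try:
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a cycle involving edge {cycle[0][0]} -> {cycle[0][1]}")
        except nx.NetworkXNoCycle:
            pass
        roots = [t for t in active if not self.parents[t]]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        for t in active:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise OntologyError(f"term {t} does not reach the root")

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def require(self, terms: Iterable[str]) -> None:
        for t in terms:
            if t not in self.parents:
                raise OntologyError(f"unknown term id {t!r}")

    @lru_cache(maxsize=None)
    def ancestors_or_self(self, term: str) -> frozenset[str]:
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self.parents[t]:
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return frozenset(out)

    @lru_cache(maxsize=None)
    def level(self, term: str) -> int:
        """Minimum-depth level; the root is level 1."""
        if term == self.root:
            return 1
        return 1 + min(self.level(p) for p in self.parents[term])

    def neighbours_one_level(self, term: str) -> frozenset[str]:
        """Parents and children: terms exactly one is_a edge away."""
        return frozenset(self.parents[term]) | frozenset(self.children.get(term, ()))


def load_obo(path: str | Path) -> Ontology:
    """Load an OBO 1.2 flat file (id, name, is_a, is_obsolete stanza tags)."""
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    parents: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    obsolete = set()
    for node, data in graph.nodes(data=True):
        names[node] = data.get("name", node)
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
        # obonet edge direction is child -> parent for is_a
        parents[node] = frozenset(graph.successors(node))
    return Ontology(parents, names, frozenset(obsolete))


def propagate_corpus(corpus: AnnotationCorpus, ontology: Ontology) -> AnnotationCorpus:
    if corpus.propagated:
        return corpus
    closed = {}
    for gene, terms in corpus.gene_terms.items():
        ontology.require(terms)
        acc: set[str] = set()
        for t in terms:
            acc |= ontology.ancestors_or_self(t)
        closed[gene] = frozenset(acc)
    return AnnotationCorpus(closed, propagated=True)


def information_content(ontology: Ontology, corpus: AnnotationCorpus) -> dict[str, float]:
    """Resnik corpus information content: ``ic(t) = -ln(n_t / N)`` where
    ``n_t`` counts genes annotated (after ancestor propagation) with ``t``
    and ``N`` is the corpus size.  Unannotated terms get ``+inf``."""
    if not corpus.gene_terms:
        raise OntologyError("annotation corpus is empty")
    corpus = propagate_corpus(corpus, ontology)
    n_genes = len(corpus.gene_terms)
    counts: dict[str, int] = {t: 0 for t in ontology.parents}
    for terms in corpus.gene_terms.values():
        for t in terms:
            counts[t] += 1
    return {
        t: (-math.log(n / n_genes) if n > 0 else math.inf)
        for t, n in counts.items()
    }


@dataclass(frozen=True)
class _MatchCounts:
    exact_count: int
    one_level_count: int
    ic2_count: int
    ic4_count: int


def match_features(
    patient_terms: Iterable[str],
    gene_terms: Iterable[str],
    ontology: Ontology,
    ic_map: Mapping[str, float],
    ic_cutoffs: tuple[float, float] = (2.0, 4.0),
):
    """Count exact and one-level patient/gene term matches.

    One-level matches pair a patient term with a gene term that is its
    direct parent or child (siblings excluded); each patient term
    contributes at most one such match.  The IC-cutoff counts apply to exact
    matches only.
    """
    from .types import HpoMatchFeatures

    patient = frozenset(patient_terms)
    gene = frozenset(gene_terms)
    ontology.require(patient | gene)
    exact = patient & gene
    one_level = sum(
        1 for p in patient if ontology.neighbours_one_level(p) & gene
    )
    lo, hi = ic_cutoffs
    return HpoMatchFeatures(
        exact_count=len(exact),
        one_level_count=one_level,
        ic2_count=sum(1 for t in exact if ic_map.get(t, 0.0) >= lo),
        ic4_count=sum(1 for t in exact if ic_map.get(t, 0.0) >= hi),
    )


def _mica_ic(a: str, b: str, ontology: Ontology, ic_map: Mapping[str, float]) -> float:
    common = ontology.ancestors_or_self(a) & ontology.ancestors_or_self(b)
    best = 0.0
    for t in common:
        ic = ic_map.get(t, 0.0)
        if math.isfinite(ic) and ic > best:
            best = ic
    return best


def similarity(
    patient_terms: Iterable[str],
    gene_terms: Iterable[str],
    ontology: Ontology,
    ic_map: Mapping[str, float],
) -> float:
    """Symmetric best-match-average Resnik similarity.

    For each term on one side take the maximum IC of a most-informative
    common ancestor with any term on the other side; average both
    directions.  An empty gene set scores 0.
    """
    patient = sorted(frozenset(patient_terms))
    gene = sorted(frozenset(gene_terms))
    if not patient:
        raise OntologyError("patient term set must be nonempty")
    if not gene:
        return 0.0
    ontology.require(patient + gene)
    fwd = sum(max(_mica_ic(p, g, ontology, ic_map) for g in gene) for p in patient) / len(patient)
    rev = sum(max(_mica_ic(g, p, ontology, ic_map) for p in patient) for g in gene) / len(gene)
    return 0.5 * (fwd + rev)


def combine_profiles(
    manual: Iterable[str], nlp: Iterable[str], ontology: Ontology
) -> PhenotypeProfile:
    """Union the manual and NLP term sets, dropping obsolete terms.

    Ancestor-redundant terms are deliberately kept: downstream features are
    counts and no redundancy-collapsing rule is imposed.
    """
    manual_set = frozenset(manual)
    nlp_set = frozenset(nlp)
    ontology.require(manual_set | nlp_set)
    clean = lambda s: frozenset(t for t in s if t not in ontology.obsolete)
    manual_clean = clean(manual_set)
    nlp_clean = clean(nlp_set)
    return PhenotypeProfile(
        manual_terms=manual_clean,
        nlp_terms=nlp_clean,
        combined_terms=manual_clean | nlp_clean,
    )


def third_level_partition(patient_terms: Iterable[str], ontology: Ontology) -> list[Branch]:
    """Group patient terms by their level-3 ancestors.

    A term joins the branch of *every* level-3 ancestor it reaches (so
    pruning one branch removes the whole phenotype cluster); terms above
    level 3 fall into a residual branch with ``anchor=None``.  Returns
    branches sorted by anchor id, residual last.
    """
    terms = frozenset(patient_terms)
    if not terms:
        return []
    ontology.require(terms)
    branches: dict[Optional[str], set[str]] = {}
    for t in terms:
        anchors = [a for a in ontology.ancestors_or_self(t) if ontology.level(a) == 3]
        if anchors and ontology.level(t) >= 3:
            for a in anchors:
                branches.setdefault(a, set()).add(t)
        else:
            branches.setdefault(None, set()).add(t)
    out = [
        Branch(anchor=a, members=frozenset(m))
        for a, m in branches.items()
        if a is not None
    ]
    out.sort(key=lambda b: b.anchor)
    if None in branches:
        out.append(Branch(anchor=None, members=frozenset(branches[None])))
    return out


def prune_branch(profile: PhenotypeProfile, branch: Branch) -> PhenotypeProfile:
    """Remove one branch's terms from a profile.

    The branch members are removed from all three term sets so the
    phenotype cluster is fully absent, emulating a patient history in which
    the cluster had not yet manifested.
    """
    if not branch.members <= profile.manual_terms:
        raise OntologyError("branch was not derived from this profile's manual terms")
    return PhenotypeProfile(
        manual_terms=profile.manual_terms - branch.members,
        nlp_terms=profile.nlp_terms - branch.members,
        combined_terms=profile.combined_terms - branch.members,
    )
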