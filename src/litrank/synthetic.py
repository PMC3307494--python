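"""Synthetic worlds for exercising the full ranking pipeline offline.

A world consists of a typed keyword dictionary, a two-topic abstract corpus
(topic A vs topic B), gene-to-abstract link tables, and ground-truth topic
labels.  Abstracts mimic the statistics of pre-tagged biomedical abstracts:
the number of keywords per abstract is Poisson-distributed with mean 32,
and keywords are drawn from per-topic multinomials whose overlap is
controlled by a single separability parameter δ ∈ [0, 1]:

* δ = 0 — both topics draw from one shared keyword distribution
  (no signal; a classifier can do no better than chance);
* δ = 1 — the topic vocabularies are disjoint (perfectly separable);
* in between, each keyword draw uses the topic-exclusive vocabulary with
  probability δ and the shared vocabulary otherwise.

Keyword weights are sampled from a Dirichlet with a concentration knob.
Synthetic genes link to abstracts of one topic (purity 1.0 by default; an
impurity knob mislinks a fraction to the other topic).  Every quantity is
drawn from a single seeded generator, so identical seeds give identical
worlds.

Abstract text is emitted by joining sampled surface forms with spaces;
surface forms are unique single tokens, so tagging the emitted text
reproduces the pre-tagged profiles exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import AbstractRecord, GeneLinkTable, write_corpus
from .tagger import KEYWORD_TYPES, DictionaryEntry, KeywordProfile, write_pretagged

#: PMID blocks for the two topics keep synthetic IDs recognizable.
_PMID_BASE = {"A": 1_000_000, "B": 2_000_000}


@dataclass
class TopicSpec:
    """Keyword-sampling recipe for one topic."""

    topic: str
    weights: dict[str, float]
    mean_keywords: float = 32.0
    n_abstracts: int = 100

    def __post_init__(self):
        if self.mean_keywords <= 0:
            raise ValueError("mean_keywords must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("keyword weights must be non-negative")
        if self.weights and not any(w > 0 for w in self.weights.values()):
            raise ValueError(f"topic {self.topic}: no keyword has positive weight")


@dataclass
class SyntheticWorld:
    dictionary: list[DictionaryEntry]
    records: dict[int, AbstractRecord]
    profiles: dict[int, KeywordProfile]
    links: GeneLinkTable
    truth: dict[int, str]  # pmid -> "A" | "B"
    delta: float
    term_types: dict[str, str] = field(default_factory=dict)
    genes_by_topic: dict[str, list[str]] = field(default_factory=dict)

    def pmids(self, topic: str) -> list[int]:
        return [p for p, t in self.truth.items() if t == topic]


def topic_weight_maps(delta: float, vocab_size: int = 200,
                      concentration: float = 1.0, seed: int = 0,
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Two topic keyword distributions with exclusive-vocabulary fraction δ.

    ``round(delta * vocab_size)`` terms per topic are exclusive, the rest are
    shared with identical weights in both topics.  Weight vectors are
    Dirichlet draws scaled so each map sums to 1.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_excl = int(round(delta * vocab_size))
    n_shared = vocab_size - n_excl

    def dirichlet(n):
        return rng.dirichlet(np.full(n, concentration)) if n else np.array([])

    shared = {f"kwsh{i:04d}": w for i, w in enumerate(dirichlet(n_shared))}
    excl_a = {f"kwta{i:04d}": w for i, w in enumerate(dirichlet(n_excl))}
    excl_b = {f"kwtb{i:04d}": w for i, w in enumerate(dirichlet(n_excl))}
    weights_a = {t: delta * w for t, w in excl_a.items()}
    weights_a.update({t: (1 - delta) * w for t, w in shared.items()})
    weights_b = {t: delta * w for t, w in excl_b.items()}
    weights_b.update({t: (1 - delta) * w for t, w in shared.items()})
    return weights_a, weights_b


def generate_world(spec_a: TopicSpec, spec_b: TopicSpec, delta: float,
                   n_genes: int = 20, seed: int = 0,
                   link_purity: float = 1.0,
                   mean_links_per_gene: float = 5.0) -> SyntheticWorld:
    """Sample a complete synthetic world from two topic specs.

    Deterministic given the seed.  Each abstract draws
    ``Poisson(mean_keywords)`` keyword tokens from its topic's multinomial;
    genes are split between the topics and link to abstracts of their own
    topic except for a ``1 - link_purity`` fraction of mislinks.
    """
    rng = np.random.default_rng(seed)
    for spec in (spec_a, spec_b):
        if not spec.weights or not any(w > 0 for w in spec.weights.values()):
            raise ValueError(f"topic {spec.topic}: no keyword has positive weight")

    all_terms = sorted(set(spec_a.weights) | set(spec_b.weights))
    term_types = {t: KEYWORD_TYPES[rng.integers(len(KEYWORD_TYPES))]
                  for t in all_terms}
    dictionary = [DictionaryEntry(t, t, term_types[t]) for t in all_terms]

    records: dict[int, AbstractRecord] = {}
    profiles: dict[int, KeywordProfile] = {}
    truth: dict[int, str] = {}
    for spec, topic in ((spec_a, "A"), (spec_b, "B")):
        terms = sorted(spec.weights)
        probs = np.array([spec.weights[t] for t in terms], dtype=float)
        probs = probs / probs.sum()
        for i in range(spec.n_abstracts):
            pmid = _PMID_BASE[topic] + i + 1
            k = int(rng.poisson(spec.mean_keywords))
            drawn = rng.choice(len(terms), size=k, p=probs) if k else []
            counts: dict[str, int] = {}
            tokens = []
            for j in drawn:
                term = terms[j]
                counts[term] = counts.get(term, 0) + 1
                tokens.append(term)
            records[pmid] = AbstractRecord(pmid, title="", body=" ".join(tokens))
            profiles[pmid] = KeywordProfile(pmid, counts)
            truth[pmid] = topic

    links = GeneLinkTable()
    genes_by_topic: dict[str, list[str]] = {"A": [], "B": []}
    topic_pmids = {t: sorted(p for p, lab in truth.items() if lab == t)
                   for t in ("A", "B")}
    for g in range(n_genes):
        topic = "A" if g < (n_genes + 1) // 2 else "B"
        entrez = str(9_000_000 + g)
        genes_by_topic[topic].append(entrez)
        n_links = 1 + int(rng.poisson(max(mean_links_per_gene - 1, 0)))
        pmid_list = []
        for _ in range(n_links):
            src = topic if rng.random() < link_purity else ("B" if topic == "A" else "A")
            pool = topic_pmids[src]
            if pool:
                pmid_list.append(int(pool[rng.integers(len(pool))]))
        links.entrez_to_pmids[entrez] = pmid_list
        links.ensembl_to_entrez[f"ENSG{900_000_000 + g:011d}"] = [entrez]

    return SyntheticWorld(dictionary, records, profiles, links, truth,
                          delta, term_types, genes_by_topic)


def default_world(delta: float, n_per_topic: int = 100,
                  mean_keywords: float = 32.0, vocab_size: int = 200,
                  concentration: float = 1.0, n_genes: int = 20,
                  seed: int = 0, link_purity: float = 1.0) -> SyntheticWorld:
    """Convenience constructor: build both topic specs and sample a world."""
    weights_a, weights_b = topic_weight_maps(delta, vocab_size, concentration, seed)
    spec_a = TopicSpec("A", weights_a, mean_keywords, n_per_topic)
    spec_b = TopicSpec("B", weights_b, mean_keywords, n_per_topic)
    # Derive the sampling seed from the weight seed so one seed fixes the world.
    return generate_world(spec_a, spec_b, delta, n_genes, seed=(seed * 7919 + 1) % (2**31))


def emit_fixtures(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture the other modules consume.

    Produces dictionary.tsv, corpus.tsv, pretagged.tsv, entrez_links.tsv,
    ensembl_links.tsv and truth.tsv under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv"
             for name in ("dictionary", "corpus", "pretagged",
                          "entrez_links", "ensembl_links", "truth")}
    with open(paths["dictionary"], "w") as fh:
        for e in world.dictionary:
            fh.write(f"{e.surface_form}\t{e.term_id}\t{e.term_type}\n")
    write_corpus(world.records, paths["corpus"])
    write_pretagged(world.profiles, world.term_types, paths["pretagged"])
    with open(paths["entrez_links"], "w") as fh:
        for gene, pmids in world.links.entrez_to_pmids.items():
            for pmid in pmids:
                fh.write(f"{gene}\t{pmid}\n")
    with open(paths["ensembl_links"], "w") as fh:
        for ensg, genes in world.links.ensembl_to_entrez.items():
            for gene in genes:
                fh.write(f"{ensg}\t{gene}\n")
    with open(paths["truth"], "w") as fh:
        for pmid in sorted(world.truth):
            fh.write(f"{pmid}\t{world.truth[pmid]}\n")
    return paths
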