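"""End-to-end ranking jobs.

A job runs the full workflow: parse the input identifier lists, expand
genes to abstracts, auto-fill a random background set B when only the
"interesting" set A is given, tag or load keyword profiles, build the A∪B
feature space, tune the penalty by the two-stage grid search, train the
final model, and score/rank the query set C.

Scoring semantics: an abstract is assigned to set A iff its relevance
probability is strictly greater than the assignment threshold (default
0.5); a score exactly at the threshold goes to B ("opposite criteria").
The A-list is ranked by descending score, the B-list by ascending score so
the most confidently-B abstracts lead; ties order by ascending PMID.

When no query set is given, C defaults to every indexed abstract (training
abstracts included) and the headline lists apply a high-confidence cutoff
(default 0.85) instead of the full listing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import corpus as corpus_mod
from .corpus import (DocumentSet, GeneLinkTable, IdKind, SetLabel,
                     UnusableSetError, enforce_input_cap, parse_identifier_list,
                     expand_to_abstracts, read_corpus)
from .features import build_feature_space, vectorize
from .model import SolverConfig, TunedModel, select_C, train_final
from .tagger import (KeywordProfile, TypeSelection, compile_dictionary,
                     load_pretagged, read_dictionary, tag_text)

logger = logging.getLogger(__name__)

DEFAULT_ASSIGNMENT_THRESHOLD = 0.5
DEFAULT_REPORT_CUTOFF = 0.85


@dataclass
class JobConfig:
    """Everything a ranking job needs; loadable from YAML."""

    set_a: list[str] = field(default_factory=list)
    set_b: list[str] = field(default_factory=list)
    set_c: list[str] = field(default_factory=list)
    kind_a: str = IdKind.entrez_gene.value
    kind_b: str = IdKind.entrez_gene.value
    kind_c: str = IdKind.pubmed_id.value
    disabled_types: list[str] = field(default_factory=list)
    score_assignment_threshold: float = DEFAULT_ASSIGNMENT_THRESHOLD
    default_report_cutoff: float = DEFAULT_REPORT_CUTOFF
    input_cap: int = corpus_mod.INPUT_CAP
    seed: int = 0
    tolerance_e: float = 0.1
    folds: int = 5
    corpus_path: str | None = None
    corpus_format: str = "fixture_tsv"
    pretagged_path: str | None = None
    dictionary_path: str | None = None
    entrez_links_path: str | None = None
    ensembl_links_path: str | None = None
    exclude_training_from_c: bool = False

    def __post_init__(self):
        for name in ("score_assignment_threshold", "default_report_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.input_cap <= 0:
            raise ValueError("input_cap must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "JobConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RankedResult:
    pmid: int
    score: float
    assignment: str  # "A" or "B"
    rank: int  # 1-based within its assignment list


@dataclass
class JobReport:
    set_sizes: dict[str, int]
    cv_accuracy: float
    test_set_accuracy: float
    chosen_C: float
    trace: list
    top_a: list[RankedResult]
    top_b: list[RankedResult]
    ranked: list[RankedResult]
    seed: int
    config: JobConfig | None = None

    def to_json(self, path: str | Path) -> None:
        def res(r: RankedResult):
            return {"pmid": r.pmid, "score": r.score,
                    "assignment": r.assignment, "rank": r.rank}

        doc = {
            "set_sizes": self.set_sizes,
            "cv_accuracy": self.cv_accuracy,
            "test_set_accuracy": self.test_set_accuracy,
            "chosen_C": self.chosen_C,
            "trace": [{"C": p.C, "cv_accuracy": p.cv_accuracy, "stage": p.stage}
                      for p in self.trace],
            "seed": self.seed,
            "top_set_a_results": [res(r) for r in self.top_a],
            "top_set_b_results": [res(r) for r in self.top_b],
            "ranked": [res(r) for r in self.ranked],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def write_ranked_tsv(results: Sequence[RankedResult], path: str | Path) -> None:
    """Ranked table TSV: ``pmid<TAB>score<TAB>assignment<TAB>rank``."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(f"{r.pmid}\t{r.score:.8f}\t{r.assignment}\t{r.rank}\n")


def read_ranked_tsv(path: str | Path) -> list[RankedResult]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        pmid, score, assignment, rank = line.split("\t")
        out.append(RankedResult(int(pmid), float(score), assignment, int(rank)))
    return out


def sample_random_background(set_a: DocumentSet, universe: Sequence[int],
                             seed: int) -> DocumentSet:
    """Auto-fill set B: |A| PMIDs sampled from the universe, disjoint from A.

    Sampling is without replacement and seeded, so a rerun with the same
    seed produces the identical background.
    """
    excluded = set(set_a.pmids)
    candidates = sorted(set(universe) - excluded)
    n = len(set_a.pmids)
    if len(candidates) < n:
        raise ValueError(
            f"universe has only {len(candidates)} abstracts outside set A; "
            f"cannot sample a background of {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return DocumentSet(SetLabel.B, [candidates[i] for i in chosen])


def default_set_c(indexed_corpus: Mapping[int, object]) -> DocumentSet:
    """Whole-index query set: every indexed abstract, A/B overlap included."""
    if not indexed_corpus:
        raise UnusableSetError("the indexed corpus is empty; cannot build a default set C")
    return DocumentSet(SetLabel.C, sorted(indexed_corpus))


def classify_and_rank(model: TunedModel, vectors_c: Sequence,
                      threshold: float = DEFAULT_ASSIGNMENT_THRESHOLD,
                      ) -> list[RankedResult]:
    """Score set-C vectors and rank them within their assignments.

    Assignment to A requires score strictly above the threshold; a score
    exactly at the threshold goes to B.  Returned in A-list order (score
    descending) followed by B-list order (score ascending); equal scores
    order by ascending PMID.
    """
    scored = [(vec.pmid, model.probability_a(vec)) for vec in vectors_c]
    a_side = sorted((x for x in scored if x[1] > threshold),
                    key=lambda x: (-x[1], x[0]))
    b_side = sorted((x for x in scored if x[1] <= threshold),
                    key=lambda x: (x[1], x[0]))
    out = [RankedResult(pmid, score, "A", i + 1)
           for i, (pmid, score) in enumerate(a_side)]
    out += [RankedResult(pmid, score, "B", i + 1)
            for i, (pmid, score) in enumerate(b_side)]
    return out


def _profiles_for(ds: DocumentSet, profile_index: Mapping[int, KeywordProfile],
                  ) -> list[KeywordProfile]:
    # Unindexed abstracts keep an empty profile; duplicates repeat.
    return [profile_index.get(p, KeywordProfile(p)) for p in ds.pmids]


def run_job(cfg: JobConfig, out_dir: str | Path | None = None) -> JobReport:
    """Run a complete ranking job from a configuration.

    Stages (any failure aborts with a stage-labeled message):
    input parsing -> abstract collection -> keyword processing -> penalty
    tuning & training -> classification -> report.
    """
    selection = TypeSelection.without(*cfg.disabled_types) if cfg.disabled_types \
        else TypeSelection.all()

    # --- stage 0/1: input parsing and abstract collection -------------------
    links = GeneLinkTable.from_tsv(cfg.entrez_links_path, cfg.ensembl_links_path)

    def collect(tokens, kind, label) -> DocumentSet | None:
        if not tokens:
            return None
        enforce_input_cap(tokens, cfg.input_cap)
        ids = parse_identifier_list(tokens, kind)
        ds = expand_to_abstracts(ids, links, label)
        enforce_input_cap(ds, cfg.input_cap)
        return ds

    try:
        ds_a = collect(cfg.set_a, cfg.kind_a, SetLabel.A)
        ds_b = collect(cfg.set_b, cfg.kind_b, SetLabel.B)
        ds_c = collect(cfg.set_c, cfg.kind_c, SetLabel.C)
    except (ValueError, KeyError) as err:
        raise RuntimeError(f"[input collection] {err}") from err
    if ds_a is None:
        raise RuntimeError("[input collection] set A is required")

    # --- stage 2: keyword processing ----------------------------------------
    try:
        if cfg.pretagged_path:
            profile_index = load_pretagged(cfg.pretagged_path, selection)
        elif cfg.corpus_path and cfg.dictionary_path:
            records = read_corpus(cfg.corpus_path, cfg.corpus_format)
            matcher = compile_dictionary(read_dictionary(cfg.dictionary_path))
            profile_index = {pmid: tag_text(rec, matcher, selection)
                             for pmid, rec in records.items()}
        else:
            raise ValueError("need either pretagged_path or corpus_path + dictionary_path")
    except (OSError, ValueError) as err:
        raise RuntimeError(f"[keyword processing] {err}") from err

    whole_index_mode = ds_c is None
    if ds_b is None:
        ds_b = sample_random_background(ds_a, list(profile_index), cfg.seed)
    if ds_c is None:
        ds_c = default_set_c(profile_index)
    if cfg.exclude_training_from_c:
        training = set(ds_a.pmids) | set(ds_b.pmids)
        ds_c = DocumentSet(SetLabel.C, [p for p in ds_c.pmids if p not in training])

    # --- stage 3: training ---------------------------------------------------
    try:
        profiles_a = _profiles_for(ds_a, profile_index)
        profiles_b = _profiles_for(ds_b, profile_index)
        space = build_feature_space(profiles_a, profiles_b)
        train_vectors = [vectorize(p, space, "A") for p in profiles_a] \
            + [vectorize(p, space, "B") for p in profiles_b]
        solver_cfg = SolverConfig(tolerance_e=cfg.tolerance_e, folds=cfg.folds)
        chosen_c, trace = select_C(train_vectors, solver_cfg, cfg.seed)
        cv_acc = max(p.cv_accuracy for p in trace)
        model = train_final(train_vectors, chosen_c, solver_cfg,
                            n_dims=space.n_dims, trace=trace,
                            cv_accuracy=cv_acc, seed=cfg.seed)
    except ValueError as err:
        raise RuntimeError(f"[training] {err}") from err

    # --- stage 4/5: classification and report -------------------------------
    vectors_c = [vectorize(p, space) for p in _profiles_for(ds_c, profile_index)]
    ranked = classify_and_rank(model, vectors_c, cfg.score_assignment_threshold)
    if whole_index_mode:
        top_a = [r for r in ranked if r.assignment == "A"
                 and r.score > cfg.default_report_cutoff]
        top_b = [r for r in ranked if r.assignment == "B"
                 and r.score < 1.0 - cfg.default_report_cutoff]
    else:
        top_a = [r for r in ranked if r.assignment == "A"]
        top_b = [r for r in ranked if r.assignment == "B"]

    report = JobReport(
        set_sizes={"A": len(ds_a), "B": len(ds_b), "C": len(ds_c)},
        cv_accuracy=model.cv_accuracy,
        test_set_accuracy=model.test_set_accuracy,
        chosen_C=chosen_c, trace=trace,
        top_a=top_a, top_b=top_b, ranked=ranked,
        seed=cfg.seed, config=cfg)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        write_ranked_tsv(ranked, out_dir / "ranked.tsv")
        model.to_json(out_dir / "model.json")
        (out_dir / "config.yaml").write_text(
            yaml.safe_dump(vars(cfg), default_flow_style=False))
    return report
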