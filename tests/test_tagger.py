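"""Dictionary compilation and longest-match tagging."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litrank.corpus import AbstractRecord
from litrank.tagger import (DictionaryEntry, TypeSelection, compile_dictionary,
                            load_pretagged, tag_text, tokenize, write_pretagged)


def entry(surface, term, ttype="bio_term"):
    return DictionaryEntry(surface, term, ttype)


def oracle_counts(text, entries):
    """Independent longest-match oracle: enumerate every dictionary substring
    occurrence, then greedily keep maximal non-overlapping matches left to
    right (longer match preferred at equal start)."""
    tokens = tokenize(text)
    forms = {}
    for e in entries:
        forms.setdefault(tuple(tokenize(e.surface_form)), set()).add(e.term_id)
    occurrences = []  # (start, length, term_ids)
    for start in range(len(tokens)):
        for length in range(1, len(tokens) - start + 1):
            key = tuple(tokens[start:start + length])
            if key in forms:
                occurrences.append((start, length, forms[key]))
    occurrences.sort(key=lambda o: (o[0], -o[1]))
    counts, blocked_until = {}, 0
    for start, length, term_ids in occurrences:
        if start >= blocked_until:
            for tid in term_ids:
                counts[tid] = counts.get(tid, 0) + 1
            blocked_until = start + length
    return counts


class TestMatcher:
    def test_simple_count(self):
        m = compile_dictionary([entry("p53", "g1", "gene_protein")])
        profile = tag_text(AbstractRecord(1, body="p53 binds p53"), m)
        assert profile.counts == {"g1": 2}

    def test_longest_match_wins(self):
        entries = [entry("cyclin E", "t1"), entry("cyclin", "t2"),
                   entry("phosphorylation", "a1", "bio_action")]
        m = compile_dictionary(entries)
        text = "cyclin E phosphorylation"
        profile = tag_text(AbstractRecord(1, body=text), m)
        assert profile.counts == {"t1": 1, "a1": 1}
        assert profile.counts == oracle_counts(text, entries)

    def test_case_insensitive_and_token_boundaries(self):
        m = compile_dictionary([entry("P53", "g1", "gene_protein")])
        assert tag_text(AbstractRecord(1, body="p53 and P53."), m).counts == {"g1": 2}
        # no match inside a longer token
        assert tag_text(AbstractRecord(1, body="ap53b"), m).counts == {}

    def test_hyphen_stays_inside_token(self):
        m = compile_dictionary([entry("S-phase", "t1"), entry("phase", "t2")])
        assert tag_text(AbstractRecord(1, body="the S-phase starts"), m).counts \
            == {"t1": 1}

    def test_ambiguous_surface_form_credits_all_term_ids(self):
        m = compile_dictionary([entry("CDK1", "gene_a", "gene_protein"),
                                entry("CDK1", "chem_b", "chemical")])
        profile = tag_text(AbstractRecord(1, body="CDK1 rises"), m)
        assert profile.counts == {"gene_a": 1, "chem_b": 1}

    def test_type_filter_applied_after_matching(self):
        entries = [entry("p53", "g1", "gene_protein"), entry("apoptosis", "b1")]
        m = compile_dictionary(entries)
        rec = AbstractRecord(1, body="p53 triggers apoptosis")
        no_genes = tag_text(rec, m, TypeSelection.without("gene_protein"))
        assert no_genes.counts == {"b1": 1}
        # disabling one type never changes remaining counts
        full = tag_text(rec, m)
        assert full.counts["b1"] == no_genes.counts["b1"]

    def test_always_enabled_types_cannot_be_disabled(self):
        with pytest.raises(ValueError):
            TypeSelection.without("bio_term")

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            compile_dictionary([])

    def test_textless_record_gives_empty_profile(self):
        m = compile_dictionary([entry("p53", "g1", "gene_protein")])
        assert tag_text(AbstractRecord(1), m).counts == {}

    def test_title_and_body_both_scanned(self):
        m = compile_dictionary([entry("kinase", "k1")])
        rec = AbstractRecord(1, title="A kinase study", body="the kinase acts")
        assert tag_text(rec, m).counts == {"k1": 2}


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from(["cyclin", "e", "kinase", "p53", "binds", "x"]),
                min_size=0, max_size=25))
def test_scan_matches_enumeration_oracle(tokens):
    """The scanner agrees with a full-enumeration longest-match oracle, and
    never counts more than the total number of substring occurrences."""
    entries = [DictionaryEntry("cyclin e", "t1", "bio_term"),
               DictionaryEntry("cyclin", "t2", "bio_term"),
               DictionaryEntry("e kinase", "t3", "bio_term"),
               DictionaryEntry("p53", "g1", "gene_protein")]
    text = " ".join(tokens)
    m = compile_dictionary(entries)
    got = m.scan(text)
    assert got == oracle_counts(text, entries)
    # total counts bounded by all (possibly overlapping) occurrences
    toks = tokenize(text)
    all_occurrences = sum(
        1 for s in range(len(toks)) for L in (1, 2)
        if tuple(toks[s:s + L]) in {("cyclin", "e"), ("cyclin",),
                                    ("e", "kinase"), ("p53",)})
    assert sum(got.values()) <= all_occurrences


class TestPretagged:
    def test_roundtrip_with_tag_text(self, tmp_path):
        entries = [entry("p53", "g1", "gene_protein"), entry("apoptosis", "b1")]
        m = compile_dictionary(entries)
        profile = tag_text(AbstractRecord(9, body="p53 p53 apoptosis"), m)
        path = tmp_path / "pretagged.tsv"
        write_pretagged([profile], {"g1": "gene_protein", "b1": "bio_term"}, path)
        loaded = load_pretagged(path)
        assert loaded[9].counts == profile.counts

    def test_nonpositive_count_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("1\tt1\tbio_term\t0\n1\tt2\tbio_term\t3\n")
        assert load_pretagged(path)[1].counts == {"t2": 3}

    def test_type_filter_at_load(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("1\tg1\tgene_protein\t2\n1\tb1\tbio_term\t1\n")
        loaded = load_pretagged(path, TypeSelection.without("gene_protein"))
        assert loaded[1].counts == {"b1": 1}

    def test_mean_keyword_count_of_typical_fixture(self, tmp_path):
        # ten profiles averaging 32 keywords each, as in real pre-tagged data
        lines = []
        sizes = [30, 34, 32, 28, 36, 31, 33, 29, 35, 32]
        for pmid, size in enumerate(sizes, 1):
            lines += [f"{pmid}\tterm{i:03d}\tbio_term\t1" for i in range(size)]
        path = tmp_path / "p.tsv"
        path.write_text("\n".join(lines) + "\n")
        loaded = load_pretagged(path)
        assert len(loaded) == 10
        assert sum(p.total() for p in loaded.values()) / 10 == pytest.approx(32)
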