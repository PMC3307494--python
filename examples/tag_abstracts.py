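"""Tag abstracts against a typed keyword dictionary.

Builds a six-entry dictionary, tags two toy abstracts, and shows how the
longest-match policy and the type filter shape the resulting keyword
profiles (the count vectors every later stage works from).
"""

from litrank import AbstractRecord, DictionaryEntry, TypeSelection, \
    compile_dictionary, tag_text

dictionary = [
    DictionaryEntry("cyclin E", "CHEBI:cycE", "gene_protein"),
    DictionaryEntry("cyclin", "CHEBI:cyc", "gene_protein"),
    DictionaryEntry("p53", "GENE:p53", "gene_protein"),
    DictionaryEntry("apoptosis", "GO:apoptosis", "bio_term"),
    DictionaryEntry("phosphorylation", "GO:phos", "bio_action"),
    DictionaryEntry("breast cancer", "MESH:brca", "disease"),
]
matcher = compile_dictionary(dictionary)

records = [
    AbstractRecord(1, title="Cyclin E phosphorylation",
                   body="Cyclin E phosphorylation precedes apoptosis; "
                        "p53 binds p53 in breast cancer cells."),
    AbstractRecord(2, title="A title-only entry."),
]

for record in records:
    full = tag_text(record, matcher)
    no_disease = tag_text(record, matcher, TypeSelection.without("disease"))
    print(f"PMID {record.pmid}: {full.counts}")
    print(f"  disease type disabled -> {no_disease.counts}")

# PMID 1: "cyclin E" wins over "cyclin" (longest match); p53 counted twice.
# Disabling the disease type removes MESH:brca but never changes other counts.
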