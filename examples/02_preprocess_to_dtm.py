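"""Turn raw review comments into a document-term matrix.

Shows each preprocessing stage on a small English corpus: cleaning,
bigram merging, stopword removal, stemming with stem completion, and the
final sparse count matrix.
"""

from revtopics import (PreprocessConfig, clean_and_tokenize, merge_bigrams,
                       preprocess_corpus, remove_stopwords, stem_and_complete)

comments = [
    "Took 50mg; the HEADACHE was awful!! Erectile dysfunction not cured.",
    "Works great, no side effects. Erections lasted longer.",
    "The side effect was a mild headache, still working fine.",
]

config = PreprocessConfig(typo_map={"viagre": "viagra"})
tokens = clean_and_tokenize(comments[0], config)
print("cleaned tokens:     ", tokens)
merged = merge_bigrams(tokens, config.bigrams)
print("bigrams merged:     ", merged)
kept = remove_stopwords(merged, config.stopword_set())
print("stopwords removed:  ", kept)
completed, stem_map = stem_and_complete([kept])
print("stem-completed:     ", completed[0])

dtm = preprocess_corpus(comments, ["r1", "r2", "r3"], config)
print()
print(f"DTM: {dtm.n_docs} documents x {dtm.n_terms} terms, "
      f"{dtm.total_tokens} tokens")
print("vocabulary (frequency-ordered):", dtm.vocabulary.terms)
print()
print("Note how 'erectile dysfunction' and 'side effect' became single "
      "tokens, and inflected forms (erections/headache...) were folded to "
      "their most frequent surface form.")
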