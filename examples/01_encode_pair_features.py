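"""Encode protein pairs as GO-term feature vectors.

Builds a four-term vocabulary, encodes one annotated pair and one pair with
an unannotated partner, and shows the {0,1,2} component semantics: 2 =
both proteins carry the term, 1 = exactly one does, 0 = neither.
"""

from ppisign import FeatureVocabulary, encode_pair

vocab = FeatureVocabulary(terms=("GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"))
terms_a = {"GO:0000001", "GO:0000002"}
terms_b = {"GO:0000002", "GO:0000003"}

vec = encode_pair(terms_a, terms_b, vocab)
print("vocabulary:", vocab.terms)
print("protein A terms:", sorted(terms_a))
print("protein B terms:", sorted(terms_b))
print("encoded vector:", vec.tolist())
print("  -> GO:0000002 is shared (2); GO:0000001/GO:0000003 one-sided (1); "
      "GO:0000004 absent (0)")

null = encode_pair(set(), terms_b, vocab)
print("unannotated partner encodes to:", null,
      "(the null rule: such instances are removed from training,")
print("  and at prediction time the pair's homolog instance substitutes)")
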