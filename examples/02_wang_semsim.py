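"""Wang GO semantic similarity on a three-term chain ontology.

The chain is root <- a <- b (both edges is_a, weight 0.8).  The S-values of
b decay geometrically toward the root and the term similarity of (b, a)
follows in closed form: (0.8+1 + 0.64+0.8) / (2.44 + 1.8) = 0.7642.
"""

from degronon.semsim import GoDag, compute_s_values, gene_similarity, term_similarity

dag = GoDag(
    terms=["root", "a", "b"],
    edges=[("a", "root", "is_a"), ("b", "a", "is_a")],
    namespace={t: "biological_process" for t in ["root", "a", "b"]},
)

print("S-values of b:", compute_s_values("b", dag))
print("sim(b, a)    :", round(term_similarity("b", "a", dag), 4))
print("sim(b, b)    :", term_similarity("b", "b", dag))

# gene-level similarity (best-match average over annotation sets)
print("gene sim {b} vs {a}      :", round(gene_similarity({"b"}, {"a"}, dag), 4))
print("gene sim {a,b} vs {a,b}  :", gene_similarity({"a", "b"}, {"a", "b"}, dag))
# identical annotation sets always score 1.0; partial overlap scores between
# the weakest term pair and 1.
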