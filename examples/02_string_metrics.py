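"""The string-similarity ensemble on biomedical label pairs.

Sim_lex = alpha*ISub + beta*QGram + gamma*Levenshtein is the acceptance
filter of the lexical stage; the token-based measures (Jaccard,
Monge-Elkan, block distance) are the features of the contextual
classifier.
"""

from ontomatch import (
    LexWeights,
    block_distance_sim,
    isub_sim,
    jaccard_words,
    levenshtein_sim,
    lexical_similarity,
    monge_elkan,
    qgram_sim,
)

pairs = [
    ("myocardial infarction", "infarction myocardial"),
    ("myocardial infarction", "heart attack"),
    ("left lung", "left lung lobe"),
    ("thoracic vertebral foramen", "lumbar vertebral foramen"),
]

header = f"{'pair':<55} {'ISub':>6} {'QGram':>6} {'Lev':>6} {'Jac':>6} {'ME':>6} {'Block':>6}"
print(header)
for a, b in pairs:
    print(
        f"{a + ' / ' + b:<55} "
        f"{isub_sim(a, b):>6.3f} {qgram_sim(a, b):>6.3f} {levenshtein_sim(a, b):>6.3f} "
        f"{jaccard_words(a, b):>6.3f} {monge_elkan(a, b):>6.3f} {block_distance_sim(a, b):>6.3f}"
    )

w = LexWeights(alpha=0.4, beta=0.3, gamma=0.3)
s = lexical_similarity({"myocardial infarction"}, {"heart attack"}, w)
print(f"\nSim_lex('myocardial infarction', 'heart attack') = {s:.3f}")
print("Below the default acceptance threshold 0.75 — which is why synonym"
      " pairs like this one need the lexicon-based extended stage.")
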