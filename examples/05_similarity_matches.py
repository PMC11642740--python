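"""Rank the riboswitches most similar to a candidate 5'UTR.

J_Sim combines three normalized distances — sequence-length difference,
dot-structure edit distance, and squared distance over the structural
feature block — into one 0-to-1 score, and the ligands of the closest
matches hint at what the candidate switch might bind.
"""

from riboscreen import featurize, fit_normalizer
from riboscreen.similarity import SimilarityContext, top_matches
from riboscreen.simulate import FixtureSpec, generate_structured, generate_unlabeled

spec = FixtureSpec(seed=1)
rs_recs, rs_ss, _ = generate_structured(spec, n=120, seed=1)
utr_recs, utr_ss = generate_unlabeled(spec, n=5, seed=2)

norm = fit_normalizer(list(rs_ss.values()) + list(utr_ss.values()))
reference = [{
    "id": r.id, "length": len(r), "dot": rs_ss[r.id].dot,
    "features": featurize(r.sequence, rs_ss[r.id], norm),
    "ligand": r.ligand,
} for r in rs_recs]
context = SimilarityContext.from_corpus(
    rs_lengths=[len(r) for r in rs_recs],
    utr_lengths=[len(r) for r in utr_recs])
print(f"corpus length span: max RS {context.max_rs_length} NT, "
      f"min {context.min_length} NT -> max D_L = {context.max_dl}")

query = utr_recs[0]
fv = featurize(query.sequence, utr_ss[query.id], norm)
top, tally = top_matches(query.id, len(query), utr_ss[query.id].dot, fv,
                         reference, context, k=3, tally=20)
print(f"\ntop matches for {query.id} ({len(query)} NT):")
for i, m in enumerate(top, 1):
    print(f"  {i}. {m.rs_id} (ligand {m.rs_ligand}): J_Sim = {m.j_sim:.3f} "
          f"[D_L={m.d_l}, D_Lev={m.d_lev}, D_struct={m.d_struct:.3f}]")
print("\nligand tally over the 20 closest riboswitches "
      "(a crude ligand hypothesis for the candidate):")
for ligand, count in tally.most_common():
    print(f"  {ligand}: {count}")
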