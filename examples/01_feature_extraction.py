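"""Encode an RNA sequence into the 74-element feature vector.

Parses a dot-bracket structure into stems, bulges, loops and hairpins,
then combines 3-mer frequencies, GC content and the normalized
structural counts into the vector the classifiers consume.
"""

from riboscreen import featurize, fit_normalizer, parse_dot
from riboscreen.features import FEATURE_NAMES
from riboscreen.structure import SecondaryStructure

seq = "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUC"
dot = "...((.(.....)))...(((....)))...((((......))))..."
ss = SecondaryStructure(dot=dot, mfe=-12.3)

decomp = parse_dot(dot)
print("structural decomposition of", dot)
print(f"  stems: {len(decomp.stems)} "
      f"(unbranched {decomp.n_unbranched_stems}, branched {decomp.n_branched_stems})")
print(f"  hairpin loops: {decomp.n_hairpins} covering {decomp.hairpin_nt} NT")
print(f"  bulges L/R: {len(decomp.bulges_left)}/{len(decomp.bulges_right)}, "
      f"internal loops L/R: {len(decomp.loops_left)}/{len(decomp.loops_right)}")
print(f"  exterior/junction unpaired NT: {decomp.n_unpaired}")

# a normalizer is fitted on the corpus being screened; here just this one
norm = fit_normalizer([ss])
vec = featurize(seq, ss, norm)
print(f"\nfeature vector: {vec.shape[0]} entries, all in [0, 1]")
for name, value in list(zip(FEATURE_NAMES, vec))[64:]:
    print(f"  {name:22s} = {value:.3f}")
print("(the first 64 entries are the 3-mer frequencies, summing to "
      f"{vec[:64].sum():.3f})")
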