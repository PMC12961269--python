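"""Relate protein abundances to what the instrument actually sees.

Proteins differ in how many observable (dye-carrying) peptides they shed,
so the distribution of reads over proteins (the *indicator* distribution q)
is a reweighting of the true abundances p by the expected observable
peptide yield E_Fo(y).  This example shows the forward and inverse
transforms and the read-level fluorescence-string mixture.
"""

import numpy as np

import fluorem as fm

d = fm.build_dictionary(fm.synthetic_proteins(), fm.DEFAULT_SCHEME)
m = 0.1                                   # dye miss rate: 10% of ideal labels dark

efo = fm.expected_observable_strings(d, m)
print("expected observable peptides per protein molecule (E_Fo):")
print(" ", np.round(efo, 2))

p = fm.sample_abundances(d.n_proteins, rng=0)
q = fm.abundance_to_indicator(p, efo)
print("true abundances p:     ", np.round(p, 3))
print("read-origin fractions q:", np.round(q, 3))
# q differs from p: high-yield proteins are over-represented among reads.

p_back, unobservable = fm.indicator_to_abundance(q, efo)
print("max |p - invert(q)|:   ", float(np.abs(p - p_back).max()))
# the inverse transform recovers p exactly (machine precision).

pfo = fm.string_distribution(p, d, m)
top = np.argsort(pfo)[::-1][:3]
print("three most likely read strings and their probabilities:")
for f in top:
    print(f"  {d.strings[f].code!r}: {pfo[f]:.3f}")
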