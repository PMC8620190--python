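"""Is preferential removal of negative edges explainable by chance?

Using the published Blanes Bay network counts: of 25230 microbial edges in
at least one environmental triplet (20334 positive, 4896 negative), the
intersection combination removed 2488, of which 1554 were negative. Under
random removal the sign split follows a multivariate hypergeometric
distribution.
"""

from ended import RandomRemovalModel, expected_removals, tail_probability

N, N_pos, N_neg, n = 25230, 20334, 4896, 2488
observed_neg = 1554

e_neg, e_pos, x_neg, x_pos = expected_removals(N, N_neg, N_pos, n)
print(f"expected under random removal: {e_neg} negative ({x_neg:.1f}), "
      f"{e_pos} positive ({x_pos:.1f})")

model = RandomRemovalModel(N=N, N_pos=N_pos, N_neg=N_neg, n=n)
p = tail_probability(model, observed_neg)
print(f"observed {observed_neg} negative removals; "
      f"P(k_neg >= {observed_neg} | random) = {p:.3e}")
# The vanishing tail probability says negative associations are removed far
# more often than chance allows: they are much more likely to be
# environmentally driven.
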