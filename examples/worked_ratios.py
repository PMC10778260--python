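"""Combine precomputed per-feature ratios and classify the response.

The three patients below are the published worked examples: the per-feature
ratios (area, CNR, peak attenuation; last fraction over first) are known,
and the combined metric R is their product, classified against the
calibrated cutoff R_C = 1.1.  R above the cutoff calls progression.
"""

from cbctresp import classify_r, combine_ratios, recist_classify

patients = [
    ("case 1", 1.04, 0.95, 0.97),
    ("case 2", 1.15, 0.97, 1.00),
    ("case 3", 0.82, 1.19, 0.97),
]
for name, ra, rc, rm in patients:
    ratios = combine_ratios(ra, rc, rm)
    call = classify_r(ratios.r, cutoff=1.1)
    print(f"{name}: R_A={ra:.2f} R_CNR={rc:.2f} R_mu={rm:.2f} "
          f"-> R={ratios.r:.2f} -> {call.value}")

# contrast with the diameter-only RECIST rule: a 15% area increase is only a
# ~7.3% diameter increase, well inside RECIST's "stable" band
d_first, d_last = 20.0, 20.0 * 1.15**0.5
print(f"RECIST on case 2 diameters ({d_first:.1f} -> {d_last:.1f} mm): "
      f"{recist_classify(d_first, d_last).value}")
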