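"""Build the upper-triangle filter bank and inspect its sub-bands.

The analysis range 4-42 Hz is decomposed into every band reachable by
sliding the lower edge in 2 Hz steps and growing the width in 4 Hz steps
from a 4 Hz minimum -- 90 overlapping sub-bands covering the theta, alpha,
beta and gamma rhythms.
"""

from utfbssp import build_utfb

spec = build_utfb(f_min=4, f_max=42, lower_step=2, width_step=4, min_width=4)

print(f"number of sub-bands: {len(spec)}")
print(f"first band: {spec[0].low_hz:g}-{spec[0].high_hz:g} Hz")
print(f"last band:  {spec[-1].low_hz:g}-{spec[-1].high_hz:g} Hz")

widths = sorted({b.width for b in spec})
print(f"distinct widths (Hz): {[int(w) for w in widths]}")

# bands that overlap the alpha rhythm (8-13 Hz)
alpha = [i for i, b in enumerate(spec) if b.overlap(8, 13) > 0]
print(f"{len(alpha)} of {len(spec)} sub-bands overlap the alpha rhythm")
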