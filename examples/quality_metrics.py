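"""Score the fixture suite with the four no-reference quality metrics.

Prints AG (mean forward-difference gradient), H (histogram entropy,
bits), SF (RMS row/column difference energy) and EI (mean ¼-scaled Sobel
magnitude) for each synthetic fixture, all on the 0..255 gray-level
scale.  The flat image scores zero everywhere; the unit-step ramp gives
the closed-form values AG = 1 and EI ≈ 2.
"""

from xrayenhance import report, standard_suite

print(f"{'fixture':<18} {'AG':>8} {'H':>8} {'SF':>8} {'EI':>8}")
for name, img in standard_suite().items():
    r = report(img, image_id=name)
    print(f"{name:<18} {r.AG:>8.3f} {r.H:>8.3f} {r.SF:>8.3f} {r.EI:>8.3f}")
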