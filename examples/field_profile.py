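"""Single-cell autoinducer field: profile, decay distances and signal range.

The steady-state field of one emitting cell is K0(r*sqrt(alpha))
normalized to 1 at the touching distance 2*r_c = 5 um.  alpha = delta/D
is the inverse squared signal range: the typical distance an AI
molecule diffuses before degrading is 1/sqrt(alpha).
"""

from quorumsim import FieldSpec, c_single, percent_decay_distance, signal_range

for alpha in (1e-3, 0.05, 1.0, 1e3):
    print(f"alpha = {alpha:g}/um^2  ->  signal range {signal_range(alpha):.3g} um")

spec = FieldSpec(alpha=0.05, r_c=2.5)
print("\nprofile at alpha = 0.05/um^2:")
for r in (0.0, 5.0, 10.0, 20.0, 50.0):
    print(f"  c({r:5.1f} um) = {c_single(r, spec):.4f}")

print("\ndistances where the field has dropped to i% of the contact value:")
for i in (50, 10, 1):
    print(f"  r_{i}% = {percent_decay_distance(spec, i):.2f} um")

# Values <= 5 um return exactly 1: overlapping cells perceive the
# touching-distance concentration (the truncation that regularizes the
# logarithmic divergence of K0 at the origin).
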