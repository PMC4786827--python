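"""Ternary encoding of conditional strategies and their response functions.

Each strategy is three anchor contribution levels (at others' average
contribution 0, 0.5 and 1), written as ternary digits; the base-3 value is
the strategy label.
"""

from mlsel_pgg import decode, encode, respond

for label in (0, 2, 5, 13, 18, 26):
    s = decode(label)
    profile = ", ".join(f"c({x:.2f})={respond(s, x):.2f}" for x in (0.0, 0.25, 0.5, 0.75, 1.0))
    print(f"Type {label:2d} ({s.ternary()}): {profile}")

s = encode((0.5, 0.0, 1.0))
print(f"\nanchors (0.5, 0, 1) encode to ternary {s.ternary()} = label {s.label}")
print("Type  5 mirrors the others' average exactly; Type 2 contributes only")
print("above an average of 0.5 and is therefore unexploitable; Type 26")
print("always contributes everything.")
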