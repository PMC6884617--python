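"""Which mass shift reports which pathway, derived from the atom maps.

Prints the fate-assignment tables for the glutamine and glucose tracers
— e.g. citrate M5 only arises via reductive carboxylation.
"""

from glutrace.readouts import classify_isotopologues, reductive_index

for tracer in ("U13C15N2-Gln", "U13C-Glc", "1-13C-Gln"):
    print(f"\n== {tracer}")
    print(classify_isotopologues(tracer).to_frame().to_string(index=False))

ratio = reductive_index(alpha_kg_concentration=2.4, citrate_concentration=1.2)
print(f"\n2-oxoglutarate/citrate ratio: {ratio:.1f}")
# A larger ratio favors the reverse isocitrate-dehydrogenase flux that
# feeds lipogenic acetyl-CoA from glutamine carbon.
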