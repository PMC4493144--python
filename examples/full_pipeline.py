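"""The full identification study on synthetic data.

Reconstructs the study conditions: a 130-reference panel, 188 larval queries
in the published three-site composition, classification by character key and
by NJ-tree placement, the 1% divergence gate, and the composition report.
With zero sequencing error both methods recover every planted truth and the
composition table reproduces the published counts exactly.
"""

from scombkey import (
    SimConfig,
    generate_query_set,
    generate_reference_panel,
    generate_second_marker_panel,
    load_survey_composition,
    run_pipeline,
)

cfg = SimConfig(seed=23, error_rate=0.0)
panel = generate_reference_panel(cfg)
panel2 = generate_second_marker_panel(cfg)
queries = generate_query_set(cfg, panel, panel2)

result = run_pipeline(
    panel.alignment, panel.taxonomy, queries.alignment,
    site_map=queries.truth.site_map, key=panel.key,
    marker2_queries=queries.marker2_alignment, key2=panel2.key,
    bootstrap=100, seed=17,
)

print(result.composition.with_totals().to_string())
print()
print(f"method agreement (key vs tree): {result.comparison.agreement_rate:.0%}")
print(f"gate failures (no ref within 1%): {len(result.comparison.gate_failed)}")
match = result.composition.counts.equals(load_survey_composition().counts)
print(f"composition equals the published survey: {match}")
print()
print("The nine gate failures are the non-scombrid outliers: no reference is")
print("within 1% divergence, so the distance method reports no match while the")
print("character key correctly leaves them unidentified.")
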