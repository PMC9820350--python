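"""Active-peptidase expression shares from midgut RPKM values.

Loads the packaged RPKM fixtures for both beetle species and recomputes
each active proline-specific peptidase's percentage of the summed
active-PSP expression. Inactive homologs (DPP 10) and broad-specificity
peptidases (LAP, CND) are excluded from the normalization.
"""

from pspkit import active_psp_percentages, expression_table, load_expression_table

for species in ("tcastaneum", "tmolitor"):
    records = active_psp_percentages(load_expression_table(species))
    print(f"\n=== {species} ===")
    print(expression_table(records).to_string(index=False))
    total = sum(r.percent_active for r in records if r.percent_active is not None)
    print(f"active-PSP percentage total: {total:.1f}")

# Each percentage is 100 * RPKM / sum(RPKM over active PSPs); the two
# dominant digestive activities in both species are DPP 4 and XPD/APP1.
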