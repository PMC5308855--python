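"""Screen every drug in a simulated reporting database for hiccup signals.

Builds a synthetic database with known planted reporting odds multipliers,
runs the table-construction pipeline and the drug-wise disproportionality
screen, and prints ROR, 95% CI, Fisher P and the signal flag per drug.
"""

import pvscreen as pv

db, truth = pv.generate_database(pv.demo_spec(n_cases=20_000, seed=1))
print(f"simulated {truth.n_cases} cases, {truth.n_event_cases} with "
      f"'{truth.event_term}'; planted multipliers: {truth.multipliers}")

deduped = pv.deduplicate(db)
records = pv.build_all_data_table(deduped.database).records
suspected = pv.filter_suspected(records)
print(f"all-data table: {len(records)} records; "
      f"suspected-medicine table: {len(suspected)} records")

results = pv.screen_drugs(suspected, truth.event_term)
print(f"\n{'drug':24s} {'a':>4s} {'ROR':>7s} {'95% CI':>16s} {'P':>10s} signal")
for r in results:
    ci = f"({r.ci_low:6.2f},{r.ci_high:7.2f})"
    print(f"{r.exposure_label:24s} {r.a:4d} {r.ror:7.2f} {ci:>16s} "
          f"{r.p_value:10.2e} {'YES' if r.is_signal else 'no'}")

# Drugs planted with multiplier > 1 should top the list with ci_low > 1;
# null drugs should scatter around ROR = 1 without flagging.
pv.volcano_plot(results, out_path="volcano_drugs.png",
                title=f"drug screen: {truth.event_term}", annotate=3)
print("\nwrote volcano_drugs.png (x = ln ROR, y = -log10 P, red line P = 0.05)")
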