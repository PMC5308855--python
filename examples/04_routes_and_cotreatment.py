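"""Stratified follow-up of one flagged drug: administration routes and co-treatment.

Replays published-scale contingency tables through the pipeline: the
per-route Fisher tests of an antiemetic against the rest of a 972,220-record
table, and the co-treatment classification of 83 unique event cases.
"""

import pvscreen as pv

# Route analysis on counts of a published route table: intravenous 6/1641
# (events/non-events), oral 2/3379, other 0/950 inside 972,220 records with
# 160 events in total.
db = pv.fixture_from_counts(6, 1641, 154, 970419, route="intravenous",
                            comparator_route="oral")
records = pv.filter_suspected(pv.build_all_data_table(db).records)
iv = pv.route_screen(records, "drug-x", "hiccups")[0]
print(f"intravenous: {iv.n_event} events / {iv.n_nonevent} non-events, "
      f"ROR = {pv.compute_ror(iv.table):.2f}, Fisher P = {iv.p_value:.2e}")
print("a P far below 0.05 with ROR >> 1: the IV route reports the event "
      "disproportionately.\n")

# Co-treatment among event cases: 16 on both drug and anti-cancer class,
# 1 on the drug alone, 24 on the class alone, 42 on neither.
fixture = pv.fixture_cotreatment(16, 1, 24, 42)
all_data = pv.build_all_data_table(fixture).records
table = pv.cotreatment_cross_tab(all_data, "hiccups", "dexamethasone",
                                 ["fluorouracil"])
pct = pv.cotreatment_percentages(table)
print(f"unique event cases: {table.n_cases}")
print(f"  drug users also on the anti-cancer class: {pct['pct_users_cotreated']}%")
print(f"  event cases not on the drug:              {pct['pct_cases_nonusers']}%")
print(f"  anti-cancer use among those non-users:    {pct['pct_class_among_nonusers']}%")
print(f"  drug users among all event cases:         {pct['pct_users_among_cases']}%")
print("nearly every drug user is co-treated, so the class effect cannot be")
print("separated from the drug in this stratum alone.")
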