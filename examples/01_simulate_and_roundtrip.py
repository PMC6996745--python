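"""Simulate a study-like EMA cohort and write/read it as CSV.

Generates 35 participants, 8 diary days and roughly 900 eating occasions with
a built-in trait-over-state elevation bias, then round-trips the two tables.
"""

from pathlib import Path

from emamotives import studylike_config, read_cohort, simulate_cohort, write_cohort

out = Path("example_output")
out.mkdir(exist_ok=True)

cohort = simulate_cohort(studylike_config(seed=1))
print(f"simulated {len(cohort.traits)} participants, {len(cohort.events)} eating occasions")
print(f"first trait profile (participant {cohort.traits[0].participant_id}):")
print("  " + ", ".join(f"{m}={v:.0f}" for m, v in list(cohort.traits[0].ratings.items())[:5]) + ", ...")

write_cohort(cohort, out / "traits.csv", out / "events.csv")
again = read_cohort(out / "traits.csv", out / "events.csv")
print(f"round-trip identical: {again == cohort}")
# The two CSVs are the interface to real data: a traits table (participant_id
# + 15 motive columns) and an events table (participant_id, day_index,
# meal_type + the same 15 columns), all ratings on the 1-4 Likert scale.
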