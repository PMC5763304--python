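"""Derive binary prognosis labels from survival follow-up at a 5-year horizon.

Patients with an event (death/recurrence) before the cutoff are the poor-
outcome class (-1); patients followed to the cutoff or beyond are good
outcome (+1); patients censored before the cutoff are excluded because
their status at the horizon is unknown.
"""

import hksvm as hk

records = [
    hk.SurvivalRecord("P01", time=2.1, event=True),   # recurrence at 2.1 y
    hk.SurvivalRecord("P02", time=7.4, event=False),  # alive at 7.4 y
    hk.SurvivalRecord("P03", time=6.0, event=True),   # event, but after the horizon
    hk.SurvivalRecord("P04", time=3.2, event=False),  # lost to follow-up at 3.2 y
    hk.SurvivalRecord("P05", time=4.9, event=True),
]

ids, y, excluded = hk.derive_labels(records, cutoff_years=5.0)
for sid, lab in zip(ids, y):
    outcome = "good outcome (+1)" if lab == 1 else "poor outcome (-1)"
    print(f"{sid}: {outcome}")
for sid in excluded:
    print(f"{sid}: excluded (censored before the 5-year horizon)")
print(f"\n{len(ids)} labelled, {len(excluded)} excluded out of {len(records)} patients.")
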