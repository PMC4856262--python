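"""Infer therapy lines from a hand-written event history.

A patient receives FOLFOX + bevacizumab, oxaliplatin is stopped after four
cycles (de-escalation: same line), and months later the regimen switches to
an irinotecan backbone with cetuximab (backbone change + biologic
replacement: a new line).
"""

import datetime as dt

from carelines import AgentEvent, segment_patient

D0 = dt.date(2010, 1, 4)


def cycle_days(first, last_exclusive, step=14):
    return range(first, last_exclusive, step)


events = []
for d in cycle_days(0, 120):                  # 5-FU + bev, ~4 months
    events += [AgentEvent("pt1", D0 + dt.timedelta(days=d), "FP_iv"),
               AgentEvent("pt1", D0 + dt.timedelta(days=d), "bevacizumab")]
for d in cycle_days(0, 56):                   # oxaliplatin, first 4 cycles only
    events.append(AgentEvent("pt1", D0 + dt.timedelta(days=d), "oxaliplatin"))
for d in cycle_days(160, 240):                # switch: FOLFIRI + cetuximab
    events += [AgentEvent("pt1", D0 + dt.timedelta(days=d), "FP_iv"),
               AgentEvent("pt1", D0 + dt.timedelta(days=d), "irinotecan"),
               AgentEvent("pt1", D0 + dt.timedelta(days=d), "cetuximab")]

for line in segment_patient(events, gap_days=30):
    bio = ",".join(sorted(line.biologics)) or "-"
    print(f"line {line.line_number}: {line.start} .. {line.end}  "
          f"backbone={line.backbone:4s}  biologics={bio}"
          f"{'  (resumption)' if line.resumption else ''}")
print()
print("Stopping oxaliplatin alone did not open a new line (the rest of the")
print("regimen continued); replacing bevacizumab and switching the backbone did.")
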