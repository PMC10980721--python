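"""Compute the four disproportionality statistics for one 2x2 table.

A drug-event pair is summarised by the contingency table
(a, b, c, d): reports of the target drug with/without the event, and
all other drugs with/without it.  Here the worked example (6, 4, 3, 8)
is evaluated with all four methods and their signal thresholds.
"""

from pvsignal import compute_signal_stats
from pvsignal.contingency import ContingencyTable

table = ContingencyTable(event_label="Somnolence", level="PT", a=6, b=4, c=3, d=8)
s = compute_signal_stats(table)

print(f"table: a={table.a} b={table.b} c={table.c} d={table.d} (N={table.n})")
print(f"ROR  = {s.ror:.2f}  (95% CI {s.ror_lo:.2f}-{s.ror_hi:.2f})   flag: {s.ror_flag}")
print(f"PRR  = {s.prr:.2f}  (95% CI {s.prr_lo:.2f}-{s.prr_hi:.2f})   chi2(Yates) = {s.chi2:.2f}")
print(f"IC   = {s.ic:.2f}   E(IC) = {s.e_ic:.2f}  IC025 = {s.ic025:.2f}   flag: {s.bcpnn_flag}")
print(f"EBGM = {s.ebgm:.2f}  (EBGM05 = {s.ebgm05:.2f})   flag: {s.ebgm_flag}")
print(f"signal under the all-four policy: {s.combined_flag}")
print()
print("The point estimates all exceed 1 (the event is reported")
print("disproportionally often with the target drug), but with only 6")
print("co-reports every lower bound stays below its threshold, so no")
print("method -- and hence not the combined policy -- declares a signal.")
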