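"""Compute the full disproportionality panel for a single 2x2 table.

The table counts reports in a spontaneous-report database: a = reports with
the drug of interest AND the adverse event, b = drug without the event,
c = event without the drug, d = neither. A reporting odds ratio (ROR) far
above 1 with a positive IC025 marks a disproportionality signal.
"""
from pvsignal import ContingencyTable, compute_signal_stats

table = ContingencyTable(a=20, b=80, c=10, d=890)
s = compute_signal_stats(table)

print(f"table a,b,c,d = {table.cells()}  (N = {table.n}, expected a = {table.expected:.2f})")
print(f"ROR  = {s.ror:.2f}  (95% CI {s.ror_ci_low:.2f}-{s.ror_ci_high:.2f})")
print(f"PRR  = {s.prr:.2f}   RRR = {s.rrr:.2f}   chi2(Yates) = {s.chi2:.2f}")
print(f"Fisher exact p = {s.p_value:.2e}")
print(f"IC = {s.ic:.3f}   IC025 = {s.ic025:.3f}")
print(f"Evans screen met: {s.evans_met}   classification: {s.classification}")
print()
print("The event is reported 22x more often with the drug than expected from")
print("the rest of the database; p < 0.05 and IC025 > 0, so this is a signal.")

# a zero cell: the ROR is reported not estimable, never silently corrected
empty = compute_signal_stats(ContingencyTable(a=0, b=100, c=50, d=5000))
print(f"\nzero-case table -> ROR: {empty.ror}, classification: {empty.classification}")
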