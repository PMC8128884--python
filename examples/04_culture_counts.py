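"""Population doublings and doubling time from culture cell counts.

PD = log2(N / N0) measures fold-expansion of the culture; PDT = I / PD is
the average time per doubling over I days in culture.  Together with the
capture MMS, the PDT places a sample on the motion–proliferation scatter.
"""

from colonyflow import CultureCount, classify, doubling_time, population_doublings

# 1.25e5 cells plated in a 35-mm dish, 5e5 harvested after 4 days
counts = CultureCount(n0=1.25e5, n=5e5, days_in_culture=4)
pd_value = population_doublings(counts)
pdt = doubling_time(pd_value, counts.days_in_culture)
print(f"N0 = {counts.n0:.3g}, N = {counts.n:.3g}, I = {counts.days_in_culture} d")
print(f"PD  = log2(N/N0) = {pd_value:.2f} doublings")
print(f"PDT = I/PD       = {pdt:.2f} days per doubling")

for mms_value in (52.0, 38.5):
    result = classify(mms_value, pdt=pdt, protocol_label="standard")
    print(f"MMS {mms_value:4.1f} μm/h → {result.verdict.value:12s} "
          f"(threshold {result.threshold:g} μm/h)")
print("A culture is screened as substandard when its MMS falls strictly")
print("below the threshold; 40 μm/h applies to the reference culture system.")
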