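"""Seasonal and regional D-UVB statistics from the packaged capital table.

Recomputes annual means (day-weighted from monthly means), cumulative
annual doses and July/December fold ratios for a few capitals, showing how
strongly vitamin-D-effective UVB varies across Europe.
"""
from duvb import metrics

table = metrics.load_table1()

print("city        annual mean   cumulative   Jul/Dec fold")
print("            [kJ/m2/day]   [kJ/m2/yr]   [x]")
for city in ("Nicosia", "Athens", "Kiev", "Dublin", "Reykjavik"):
    mon = metrics.table1_monthly_stats(city, table)
    annual = metrics.annual_mean_from_monthly(mon)
    cumulative = metrics.table1_annual(city, table)[0] * 365.0
    fold = mon.table.loc[7, "mean"] / mon.table.loc[12, "mean"]
    print(f"{city:<12}{annual:>8.2f}{cumulative:>13.0f}{fold:>13.1f}")

print()
print("The annual mean diurnal dose spans almost five-fold between the")
print("southern- and northern-most capitals, and within a single city the")
print("July mean exceeds the December mean by one to two orders of magnitude.")
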