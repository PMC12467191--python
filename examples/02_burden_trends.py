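"""Percent-change arithmetic on the published GBD 2021 summary rates.

Loads the packaged global / SDI-quintile age-standardized rates for neoplasms
and COPD (1990 and 2021) and recomputes the headline percent declines and the
low-vs-high SDI burden ratio.
"""

from fibroburden.trends import (
    burden_ratio,
    load_gbd_summary_rates,
    round_half_away,
    summary_table,
)

COPD = "Chronic obstructive pulmonary disease"
rates = load_gbd_summary_rates()
groups = ["Global", "High SDI", "High-middle SDI", "Middle SDI",
          "Low-middle SDI", "Low SDI"]
table = summary_table(rates, ["Neoplasms", COPD], groups, years=(1990, 2021))

for group, cause, measure in [("Global", "Neoplasms", "dalys"),
                              ("Global", COPD, "deaths"),
                              ("Global", COPD, "dalys"),
                              ("High-middle SDI", COPD, "deaths"),
                              ("Low SDI", "Neoplasms", "dalys")]:
    row = table.query("group == @group and cause == @cause and measure == @measure").iloc[0]
    print(f"{group:16s} {cause[:9]:9s} {measure:6s}: "
          f"{row['v_start']:8.2f} -> {row['v_end']:8.2f} per 100,000 "
          f"({round_half_away(row['percent_decline']):.2f}% decline)")

low = table.query("group == 'Low SDI' and cause == @COPD and measure == 'dalys'")["v_end"].iloc[0]
high = table.query("group == 'High SDI' and cause == @COPD and measure == 'dalys'")["v_end"].iloc[0]
print(f"\nlow-SDI / high-SDI COPD DALY rate ratio in 2021: "
      f"{round_half_away(burden_ratio(low, high))} (burden >3x higher in the "
      "least developed quintile)")
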