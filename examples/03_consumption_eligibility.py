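"""Aggregate a week of remote drinking reports and apply the baseline
harmful-drinking eligibility rules."""

from eftrial import DailyRecord, baseline_eligibility, summarize_phase

week = [DailyRecord("P1", i + 1, "baseline", d)
        for i, d in enumerate([4, None, 5, 6, 0, 4, 4])]

s = summarize_phase(week)
print(f"total drinks {s.total_drinks} over {s.total_days} calendar days "
      f"({s.reported_days} reported, {s.drinking_days} drinking days)")
print(f"drinks/day (calendar denominator)  = {s.drinks_per_day:.2f}")
print(f"drinks/day (reported denominator)  = {s.drinks_per_reported_day:.2f}")
print(f"drinks/drinking day                = {s.drinks_per_drinking_day:.2f}")

eligible, reasons = baseline_eligibility(week)
print("eligible to continue:", eligible, reasons or "")
# Continuation requires >=5/7 reported days, >=4 drinking days, and either
# >=4 heavy (4+ drink) days or an average above 4 drinks per drinking day.
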