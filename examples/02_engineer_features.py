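"""Window feature engineering: one row per BP reading.

Every reading is summarized by the preceding 24/48/72-hour windows (step
totals vs daily averages, active-level minutes from heart-rate zones, sleep
durations and timing, heart-rate statistics) plus the 1-hour heart rate and
the measurement clock time.
"""

from wearbp.features import build_feature_table
from wearbp.synthetic_data import SimProfile, simulate_subject

ds, _ = simulate_subject(SimProfile(days=30), seed=2)
table = build_feature_table(ds, horizon_shift=0)

print(f"{len(table)} rows x {len(table.feature_names)} features "
      f"({table.n_dropped} readings dropped for missing look-back)")
row = table.df.iloc[-1]
print(f"reading at {row['timestamp']}  SBP {row['sbp']:.1f} / DBP {row['dbp']:.1f} mmHg")
for name in ("steps_24", "steps_48", "very_active_24", "sleep_24",
             "bed_time_24", "up_time_24", "heart_rate_1", "measure_time"):
    print(f"  {name:>16} = {row[name]:8.2f}")
# steps_24 is the raw 24-h total; steps_48 the average daily total over 48 h.
# bed_time is on a shifted clock (23.5 = 23:30, 24.5 = 00:30 past midnight).
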