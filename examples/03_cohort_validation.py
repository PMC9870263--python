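"""Run the full method-agreement battery on a synthetic cohort.

Simulates 20 participants with realistic sensor noise (mounting offsets,
drift, soft-tissue artifact, T2 attachment degradation), validates the
sensor-derived angles against the camera-like reference, and prints the
across-participant summary plus the T1-vs-T2 comparisons for the knee.
"""

from rollgait import RunConfig, simulate_cohort
from rollgait.pipeline import analyze_cohort

config = RunConfig()
records = simulate_cohort(n_participants=20, seed=11, noise=True)
result = analyze_cohort(records, config)

cols = ["joint", "timepoint", "variant", "m_dif_mean", "rpc_mean",
        "r2_mean", "m_mean", "b_mean", "mae_mean", "rmse_mean"]
print("Across-participant means (zeroed sensor vs reference):")
print(result.summary[cols].round(2).to_string(index=False))

print("\nPaired T1-vs-T2 tests, knee, raw reference variant:")
for c in result.comparisons[("knee", "raw")]:
    flag = "*" if c.significant else " "
    print(f"  {c.metric:>5s}: T2-T1 = {c.mean_diff:+6.2f} +/- {c.sd_diff:5.2f}, "
          f"p = {c.p_value:.4f} {flag}")

print(f"\npooled samples per joint/timepoint: "
      f"{result.pooled['knee|T1|raw']['n']}")

# Bias (m_dif) is near zero at T1 and shifts at T2 for the knee (the
# simulated tape degradation sits on the thigh sensor); MAE/RMSE rise
# from T1 to T2 and the knee regression intercept change is flagged
# significant — the qualitative stability pattern the battery is built
# to detect. Starred rows are significant at alpha = 0.05.
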