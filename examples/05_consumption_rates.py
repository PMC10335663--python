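"""Phase segmentation and diffusion-corrected consumption rates.

Simulates a full campaign end-to-end (kinetics -> diffusion -> optode
response -> camera noise -> frames), runs the complete analysis pipeline,
and compares recovered zero-order consumption rates with the configured
truth, with and without correcting for oxygen leaking in through the tube.
"""

from pyoptode import (
    ScenarioConfig,
    build_timeseries,
    estimate_rates,
    extract_roi_ratios,
    mask_outliers,
    segment_phases,
    simulate_campaign,
)

cfg = ScenarioConfig(n_tubes=3, seed=11)
res = simulate_campaign(cfg)

samples = []
for t, frame in zip(res.times_min, res.frames):
    samples.extend(extract_roi_ratios(frame, res.layout, t))
series = build_timeseries(samples, res.cal_truths, env=cfg.env, reactors=res.reactors)

print(f"{'tube':8s} {'phases':32s} {'truth':>6s} {'corrected':>10s} {'raw':>7s}")
for tube_id, s in series.items():
    s.qc_mask = mask_outliers(s)
    seg = segment_phases(s)
    corr = estimate_rates(s, seg, correct_diffusion=True)
    raw = estimate_rates(s, seg, correct_diffusion=False)
    truth = res.tube_truths[tube_id].zero_order_slope
    print(
        f"{tube_id:8s} {'/'.join(seg.phase_labels):32s} "
        f"{truth:6.2f} {corr.zero_order_slope:10.2f} {raw.zero_order_slope:7.2f}"
    )

print("\nRates in mg/(L*hr).  The raw (uncorrected) rate understates the truth")
print("because ambient oxygen leaks into the sub-saturated tube while it is")
print("being consumed; the correction adds the modelled influx back in.")
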