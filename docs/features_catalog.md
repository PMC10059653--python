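# Feature catalog

One row per catalog entry; names as they appear in feature tables
(channel-prefixed, except `bpnn50` which keeps its canonical name).
Counts per family: time domain 24 EDA + 18 pulse; frequency domain 6 per
channel (one shared implementation); physiological 7 EDA + 10 pulse.

## Time domain — EDA (24)

| name | definition |
|---|---|
| eda_mean / eda_std / eda_var / eda_median | moments and median of the window samples |
| eda_min / eda_max / eda_range | extrema; range = max − min |
| eda_iqr | interquartile range |
| eda_skew / eda_kurtosis | standardized 3rd / excess 4th moment |
| eda_rms | root mean square |
| eda_mad | median absolute deviation |
| eda_p10 / eda_p90 | 10th / 90th percentile |
| eda_zcr | zero-crossing rate of the mean-centred window |
| eda_1dmean | mean first difference (signed; = (x_N − x_1)/(N−1)) |
| eda_1dabsmean / eda_1dstd / eda_1dmax | mean abs / SD / max abs first difference |
| eda_2dmean / eda_2dabsmean / eda_2dstd | second-difference statistics |
| eda_slope | least-squares linear slope (per sample) |
| eda_energy | sum of squared mean-centred samples |

## Time domain — pulse (18)

Same definitions as above for: mean, std, var, median, min, max, range, iqr,
skew, kurtosis, rms, 1dmean, 1dabsmean, 1dstd, 2dmean, 2dabsmean, zcr, slope
(prefixed `ppg_`).

## Frequency domain (6 per channel, shared implementation)

| name | definition |
|---|---|
| {ch}_total_power | integrated periodogram of the mean-centred window |
| {ch}_bp_low / _bp_mid / _bp_high | band power in 0–0.5 / 0.5–2 / 2–5 Hz |
| {ch}_spectral_centroid | power-weighted mean frequency |
| {ch}_spectral_entropy | normalized Shannon entropy of the spectrum |

## Physiological — EDA (7)

| name | definition |
|---|---|
| eda_scr_count | phasic peaks above 5 % prominence over the tonic estimate |
| eda_scr_amp_mean / eda_scr_amp_max | mean / max phasic peak amplitude |
| eda_scr_rise_mean | mean rise time from peak base (s) |
| eda_tonic_mean | mean of the moving-minimum tonic estimate |
| eda_tonic_slope | linear slope of the tonic estimate (units/s) |
| eda_phasic_power | mean squared phasic component |

## Physiological — pulse (10)

| name | definition |
|---|---|
| ppg_hr_mean | mean heart rate (bpm) from in-window intervals |
| ppg_ibi_mean / ppg_sdnn | mean / SD of inter-beat intervals (ms) |
| ppg_rmssd | RMS of successive interval differences (ms) |
| bpnn50 | fraction of successive interval differences with \|Δ\| > 50 ms |
| ppg_main_amp_mean | mean main-wave amplitude |
| ppg_dicrotic_amp_mean / ppg_notch_amp_mean | mean dicrotic-wave / notch amplitude |
| ppg_dicrotic_main_ratio | dicrotic-wave to main-wave amplitude ratio |
| ppg_t_peak_to_notch_mean | mean time from main peak to notch (s) |

Pulse physiological features are absent (empty, never zero) in windows with
fewer than three delineated beats; constant windows yield absent values for
that channel's sample-statistics features.
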