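# Cohort-calibrated generator defaults.
# Values mirror the published summary statistics of the reference cohort
# this package's analyses were designed around: device sleep onset just
# after midnight with ~70 min between-participant spread, ~7 h 08 min
# device sleep spans, ~58 min nightly awake time, diary sleep amounts
# running ~19 min long on self-rated good nights (SD ~46 min), and
# roughly half of diary times heaped onto :00/:30.
n_participants: 543
nights_per_participant: 14
fitbit_onset_mean_min: 19.7      # minutes after midnight (00:19:42)
fitbit_onset_sd_min: 69.7        # between participants
onset_night_sd_min: 40.0         # night-to-night within participant
fitbit_tst_mean_min: 427.97      # 7:07:58 device sleep span
fitbit_tst_sd_min: 52.8
tst_night_sd_min: 45.0
waso_mean_min: 58.0
waso_sd_min: 24.0
sol_mean_min: 15.0
device_noise_sd_min: 0.0
report_bias_good_min: 19.2       # diary - device sleep amount, good nights
report_bias_poor_min: -2.5       # diary - device sleep amount, poor nights
report_bias_sd_min: 45.9         # 90 / 1.96
report_onset_bias_mean_min: 8.65 # diary onset runs late
report_onset_bias_sd_min: 29.6   # 58.1 / 1.96
report_offset_bias_mean_min: -5.63
report_offset_bias_sd_min: 29.1  # 57.1 / 1.96
participant_bias_sd_min: 20.0
heap_prob_30: 0.49               # gives ~57.6% of values on :00/:30
qos_good_prob: 0.70              # ~4380 of 6276 nights rated good
qos_latent_strength: 1.0
ampm_error_rate: 0.01
order_error_rate: 0.01
missing_chat_rate: 0.05
missing_fitbit_rate: 0.03
psqi_good_prob: 0.586            # 318 of 543 participants
psqi_missing_rate: 0.018
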