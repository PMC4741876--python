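# Default founder-contribution run: day 14 -> day 60, 70-hour steps,
# initial class counts proportional to the day-14 size split (8% / 16% / 76%).
seed: 0
replicates: 100
start_days: 14.0
horizon_days: 60.0
initial_counts: {S: 80, M: 160, G: 760}
interpolate: false
medium_depolyploidization: false
fusion_enabled: true
multi_daughter_class: S
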