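"""Track raw vs emotion-weighted pain over a 60 s expression episode.

A single-emotion landmark series (amplitude following a raised sinusoid)
is scored frame by frame. For sadness the weighted trajectory is exactly
1.7x the raw one; for happiness it never exceeds the raw trajectory.
"""

import painface as pf

cfg = pf.default_zone_config()
cal = pf.default_calibration(cfg)
W = pf.default_weight_matrix()
table = pf.default_weight_table()
tpl = pf.make_template(seed=7, cfg=cfg)

for emotion in ("sadness", "happiness"):
    series = pf.make_temporal_series(emotion, duration=60, fps=1, tpl=tpl, cal=cal)
    prof = pf.temporal_profile(series, cfg, cal, W, table)
    ratio = (prof["plew"] / prof["ps"]).round(3).unique()
    print(f"{emotion:10s}: ps range [{prof['ps'].min():.2f}, {prof['ps'].max():.2f}], "
          f"plew/ps ratio {ratio}")
print("\nfirst five sadness timestamps:")
series = pf.make_temporal_series("sadness", duration=60, fps=1, tpl=tpl, cal=cal)
prof = pf.temporal_profile(series, cfg, cal, W, table)
print(prof.head().round(2).to_string(index=False))
# The constant plew/ps ratio is the emotion-pain weight of the detected
# expression; weighting can move frames across pain-level boundaries.
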