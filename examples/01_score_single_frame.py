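"""Score one activated frame against its neutral reference.

Builds a synthetic canonical face, applies a sadness expression at
intensity 4, and runs the full pipeline: zone displacements -> AU
intensities -> expression classification -> raw and emotion-weighted
pain scores -> pain level.
"""

import painface as pf

cfg = pf.default_zone_config()
cal = pf.default_calibration(cfg)
W = pf.default_weight_matrix()
table = pf.default_weight_table()

tpl = pf.make_template(seed=7, cfg=cfg)
active = pf.apply_activation(
    tpl, {au: 4.0 for au in pf.EMOTION_PROTOTYPES["sadness"]}, cal
)
score = pf.compute_pain(tpl.landmarks, active, cfg, cal, W, table)

print(f"frame          : {score.frame_id}")
print(f"expression     : {score.emotion} (p = {score.p_emotion.p[score.emotion]:.3f})")
print(f"PSPI baseline  : {score.pspi:.2f}   (AU4 + max(AU6,AU7) + max(AU9,AU10) + AU43)")
print(f"zone-max Ps    : {score.ps:.2f}   (sum of the six per-zone maxima, 0-30)")
print(f"weighted PLEw  : {score.plew:.2f}   (Ps x {table.w[score.emotion]}, the sadness weight)")
print(f"pain level     : {score.level} ({score.level_name})")
# A sadness expression activates three pain zones at intensity 4, so the
# raw score is 12; the sadness weight 1.7 raises it to 20.4, moving the
# frame from level 2 (moderate) into level 4 (very severe).
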