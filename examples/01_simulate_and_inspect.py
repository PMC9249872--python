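"""Render one synthetic multispectral trial and inspect its ground truth.

Builds a subject with a known heart rate, renders the five channel stacks
(R, G, B, NIR as 8-bit gray, LWIR in °C) and prints what the forward model
put into them.
"""

import numpy as np

from tstms import OpticsModel, SubjectProfile, default_class_templates, render_recording

profile = SubjectProfile(
    subject_id="demo", gender="F", heart_rate_hz=1.25,
    skin_base_intensity={"R": 150, "G": 160, "B": 140, "NIR": 150},
    base_temp_c=34.5, phase_map_seed=1,
)
templates = default_class_templates()
rec = render_recording(profile, templates["A"], OpticsModel(), seed=0)

print("channels:", {ch: arr.shape for ch, arr in rec.channels.items()})
print("true heart rate:", rec.meta["true_heart_rate_hz"], "Hz")
r0, c0, r1, c1 = rec.face_bboxes["G"]
pixel = rec.channels["G"][:, (r0 + r1) // 2, (c0 + c1) // 2].astype(float)
print(f"green face pixel: mean {pixel.mean():.1f}, swing {np.ptp(pixel):.1f} gray levels")
t0, t1, t2, t3 = rec.face_bboxes["LWIR"]
print("LWIR face/background at t=0:",
      round(float(rec.channels["LWIR"][0, (t0 + t2) // 2, (t1 + t3) // 2]), 2),
      "/", round(float(rec.channels["LWIR"][0, 2, 2]), 2), "°C")
# The pixel swing is the rendered pulsatile amplitude (blood-volume
# modulation); the LWIR split across 30 °C is what face segmentation uses.
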