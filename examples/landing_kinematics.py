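"""Recover the pre-contact deceleration onset of a landing mosquito.

Generates clean landing approaches with a programmed deceleration that
begins exactly 40 mm (along the flight path) before touching the net
roof, extracts the 65-point landing window (contact at point 51), and
locates the deceleration onset.  The onset distance and the flight speed
at onset are the quantities used to ask whether mosquitoes sense a net
before touching it.
"""

import numpy as np

from netflight import ClassifierConfig, extract_landing_window
from netflight.contacts import ContactEvent
from netflight.simulate import generate_landing_track

config = ClassifierConfig()
dists, speeds = [], []
for seed in range(25):
    track, truth = generate_landing_track(speed=350.0, decel_start_mm=40.0,
                                          seed=seed)
    contact = ContactEvent(track.track_id, truth["contact_frame"],
                           truth["contact_frame"] / 50.0, 0.0, 0.0, "turn")
    window = extract_landing_window(track, contact, config)
    dists.append(window.onset_distance_mm)
    speeds.append(window.onset_speed_mm_s)

print(f"programmed onset: 40.0 mm at 350 mm/s cruise")
print(f"recovered onset distance: {np.mean(dists):.2f} mm "
      f"(mean over {len(dists)} tracks)")
print(f"recovered speed at onset: {np.mean(speeds):.1f} mm/s")
print("the onset is the point closest to the net from which speed falls "
      "monotonically until contact; onsets within the 3 mm tarsal zone "
      "would be classed as contacts without deceleration")
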