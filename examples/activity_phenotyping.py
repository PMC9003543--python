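"""Occupancy counting and standing-vs-exercising calls from keypoints.

Generates a 180-frame session in which one, two, then three subjects stand
and then exercise, counts people per frame from the non-zero keypoint
arrays, and classifies each subject's activity from the IQR of
frame-to-frame hand-keypoint displacement.
"""

from ambientkit.posekit import classify_subjects, occupancy_accuracy, occupancy_series
from ambientkit.synthgen import KeypointSimConfig, synth_keypoints, synth_occupancy_session

cfg = KeypointSimConfig(n_subjects=3, seed=3)
frames, truth = synth_occupancy_session(cfg)
counts = occupancy_series(frames)
print(f"occupancy accuracy over {len(frames)} frames: "
      f"{100 * occupancy_accuracy(counts, truth):.0f}%")

for activity in ("standing", "exercising"):
    session, _ = synth_keypoints(cfg, activities=(activity,) * 3)
    print(f"\n{activity} subjects:")
    for k, call in enumerate(classify_subjects(session, 3, threshold=5.0)):
        print(f"  subject {k}: mean hand-keypoint IQR = {call.mean_iqr:5.2f} px "
              f"-> {call.label}")

print("\nStanding jitter keeps displacement IQRs under 5 px; arm-exercise")
print("oscillation pushes them well above, so the threshold rule separates")
print("the two activities perfectly on these tracks.")
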