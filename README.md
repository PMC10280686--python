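# walkspeed

Ground-referenced pedestrian walking speeds from nadir video taken by a
**moving** aerial camera (a drone flying along a street).

Walking speed is a basic kinematic trait — a health indicator in human
biology and the core parameter of pedestrian micro-models — but measuring it
over a whole street normally needs camera networks, timing gates or wearable
sensors. A single drone flying overhead sees everyone at once; the catch is
that every pixel moves, because the camera does. `walkspeed` turns
multi-object pedestrian tracks from such footage into metric walking speeds
by removing the camera's own motion and the perspective bias caused by
pedestrian height.

## Method

For each stride of `n` frames (default 1 s):

1. **Background motion.** Ground-feature correspondences between frames
   (from any keypoint detector; a mutual nearest-neighbour matcher under the
   angular distance is included) are fitted with a plane homography `H` by
   RANSAC (4-point DLT samples, squared symmetric transfer error, refit on
   the consensus set), since a nadir view of flat ground maps between frames
   exactly by a homography.
2. **Ground-referenced displacement.** `S₂ = X₂ − H(X₁)` for track positions
   `X₁, X₂` (bounding-box centres), i.e. the pedestrian's image motion with
   the ground's panning removed.
3. **Metric speed.** `v_m = (L/M) · ‖S₂‖ · fps / n`, where the ground
   footprint length `L = d·l/√(l²+w²)` follows from the field-of-view
   diameter `d = 2·H·tan(FOV/2)` at altitude `H`, and `M` is the long-side
   pixel count (0.0327 m/px at 40 m with an 84° FOV at 1920×1080).
4. **Relief correction.** Under central projection a head at height `h` is
   displaced radially outward by `δ = r·h/H` (`r` = signed image distance
   from the centre along the flight axis). Its change over the stride adds a
   spurious speed `v_c = (r₂−r₁)·h·fps·L·cosθ / (n·H·M)`, with `θ` the angle
   between flight and walking directions; the corrected speed is
   `v_m − v_c`, clamped at zero. The `(r₂−r₁)` term is projected onto the
   walking direction, which makes the correction exact in the ideal geometry
   whichever way drone and pedestrian move relative to each other.

A per-track speed is the median over strides. A synthetic scene simulator
(pin-hole camera over a flat ground plane, pedestrians of known height and
speed, noisy feature matches with gross outliers) provides exact ground
truth for every stage.

## Worked example

Simulate a drone at 3 m/s and 40 m over ten random pedestrians, run the
estimation pipeline, and compare with the ground truth:

```bash
cat > scene.yaml <<EOF
altitude_m: 40
drone_speed_m_s: 3.0
duration_s: 8.0
seed: 42
random_pedestrians: 10
EOF
walkspeed simulate --config scene.yaml --out sim/
walkspeed estimate --tracks sim/tracks.txt --matches sim/matches.csv --out est/
walkspeed evaluate --estimates est/track_summary.csv --truth sim/truth.csv --out summary.csv
```

which prints

```
simulated 241 frames, 10 visible tracks -> sim
estimated 60 strides over 10 tracks; 240 frame pairs (0 below consensus)
n=10; mean error +0.005 m/s; 0.05 m/s: 100.0%; 0.1 m/s: 100.0%
```

All ten estimated track speeds land within 0.05 m/s of the true walking
speeds, with a +0.005 m/s mean signed error; `est/track_summary.csv` holds
the per-track medians (e.g. track 1: 0.874 m/s corrected vs 0.780 m/s raw —
here the raw estimate was biased low because the pedestrian walks with the
drone) and `est/speeds.csv` every per-stride estimate with its correction
terms (`r₁, r₂, δ₁, δ₂, θ, v_c`).

Track files are plain text, one observation per line:
`frame id bbox-x bbox-y bbox-w bbox-h` (MOT corner convention; switchable to
centre coordinates). Matches are CSV (`frame_a, frame_b, xa, ya, xb, yb`).

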