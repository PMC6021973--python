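# Methods

This note records the detection model the package implements, the
parameters it uses, what the synthetic data generator does and does not
model, and the numerical and design decisions that are not obvious from the
code.

## Detection model

A single depth sensor hangs from the ceiling, 3 m above the floor, looking
straight down. Frames are 320×240 grids of sensor-to-surface distances in
millimetres (uint16; 0 marks a pixel with no measurement) at 30 fps.

**Segmentation.** The empty scene (floor plus furniture) is modelled as the
per-pixel median of a person-free sequence. A pixel is foreground when it is
more than 80 mm nearer to the sensor than the background. 8-connected
components of at least 150 px become candidate blobs. The person is
acquired among blobs by anthropometric gates — area between 400 and
8000 px, head at least 300 mm above the floor — and then followed from
frame to frame by mask overlap, so a lying person (who would fail the
height gate) remains tracked. When the person's blob merges with an
object's (a "fusion" event: the person disappears while the blob count
grows), the person is recovered by comparing candidate depth histograms
with the person's last histogram (L1 distance on unit-sum vectors,
threshold 0.5).

**Head distance.** The monitored scalar is `act_dist`, the sensor-to-head
distance, estimated as the mean of the 25 smallest valid depths in the blob
(the head cap in a top view). When the person is first seen upright, the
median of the first five estimates is stored as the standing reference
`pers_dist`. If the very first sighting is already past the near-floor
threshold, enrolment is refused: no upright reference exists and the person
is never recognised (this is a documented failure mode, not an error).

**Rules.** With `thresholdFall = SensorHeight − FloorDistance` (2400 mm at
defaults) and `th_var = 0.15 (SensorHeight − pers_dist)`:

1. *Near floor*: `act_dist > thresholdFall` (strict). Sustained
   continuously for more than `warning_time` (1 s) it raises a Warning, and
   for more than `recovery_time` (2 s) a Fall. The dwell clock is clamped
   at `wind_time` (3 s); at the default configuration the clamp is inert
   because `recovery_time < wind_time`.
2. *Tolerance*: `th_var` as above.
3. *Recovery*: `|act_dist − pers_dist| < th_var` or
   `act_dist < pers_dist`. After a raised Fall this downgrades it to a
   Warning — the person got up.
4. *Low posture*: `act_dist − pers_dist > th_var`. Sustained for more than
   `shift_time + sit_time` (1 s + 3 s) it hands the last `sit_time` seconds
   of buffered person frames to the SVM frame classifier. A Fall answer
   raises a Fall exactly like rule 1; an ADL answer drops `wait_time` (1 s)
   of frames from the buffer and suspends re-evaluation until the episode
   ends.

A single frame failing a condition resets that condition's episode clock
("continuously"). Every detected fall appends a 1 to a flag array, every
classifier ADL answer a 0; the sequence verdict is Fall when ones
outnumber zeros and the final state is an undowngraded Fall, Warning when a
fall was downgraded or a Warning was raised, ADL otherwise.

Rule 1 separates lying falls from everything upright; the classifier exists
for the postures rule 1 cannot decide — a person on their knees or sitting
on the ground sits right at the threshold, indistinguishable by height from
someone sitting on a chair or sofa.

### Design decisions worth recording

- **Classifier falls are downgradable.** A Fall raised through rule 4 sets
  the same fall condition as rule 1 and can therefore be downgraded by
  rule 3. This is the only reading under which a knee fall followed by
  recovery can end as a Warning, since rule 1 never fires for knee-height
  postures.
- **The `wind_time` clamp applies only to the rule-1 clock.** Applying it
  to the rule-4 clock would cap that dwell at 3 s and the 4 s evaluation
  window could never be reached, disabling the classifier pathway entirely.
- **Anthropometric gates apply at acquisition only.** Once tracked, the
  person is followed by overlap; gating every frame would drop the person
  the moment they lie down.
- **Within a frame** the order is: rule-1 events, then the rule-4
  classifier, then the rule-3 downgrade. Timestamp comparisons are strict
  (`dwell > window`), computed on the frame timestamps as given.

## DVH features and classifier

The Depth Values Histogram (DVH) of a person blob is a 256-bin histogram of
its valid depths, clamped to `[0, SensorHeight]`, normalised by
`SensorHeight` before binning (`bin = min(floor(256 · d / H), 255)`), and
normalised to unit sum. It depends only on the multiset of depth values,
so it is exactly invariant under pixel permutation and right-angle rotation
— the properties the tests pin down. A uniform blob at half the sensor
height lands in bin 128; a blob at the floor in bin 255.

Frames are classified individually by a standardise-then-linear-SVM
pipeline (scikit-learn `StandardScaler` + `LinearSVC`, C = 1) and a strict
majority over the window decides the answer. Frame labels are inherited
from the sequence ground truth, an approximation the majority vote absorbs.
Class balancing before training offers seeded subsampling, rotation
replication (kept for fidelity to the original recipe although rotated
DVHs are identical), and the default depth-jitter augmentation: bin counts
blurred by a 10 mm Gaussian and multinomially resampled at the blob's pixel
count.

The unit-sum normalisation of the DVH was chosen over raw counts so that
histograms are comparable across blob areas (a person's blob shrinks when
partially out of view) and so the association distance is scale-free.

## Synthetic data

The 800-sequence acquisition campaign behind the published figures (20
subjects × 32 fall actions × 8 ADL actions) was never deposited, so the
package renders protocol-conformant synthetic sequences instead: a flat
floor 3 m below the sensor, a chair and a sofa, and a person blob
(posture-dependent elliptical footprint with a 9 px head cap, body surface
150 mm below the head) following scripted head-height trajectories at an
orthographic 10 mm/px scale, with 10 mm Gaussian depth noise and a 30 %
dropout band on a 6 px border.

Scope and limits: the renderer reproduces the quantities the detector
observes — head distance over time and the blob's depth distribution — and
nothing else. There is no articulated body, no occlusion except at frame
borders, no sensor-specific noise model. Trajectory timings are simulator
conventions (the study reports no fall kinematics), chosen so scripted
actions land on the intended side of each temporal window with margin:
falls descend in 0.7 s and stay down 5 s (3 s before recovering in the
recovery variants); bends and squats hold about 1 s so their low-posture
episode stays under the 4 s window; furniture sits hold 4.5 s so the
classifier is exercised and must answer ADL. Every sequence's randomness
derives from a per-sequence seed hashed from (master seed, subject id,
action code), so datasets can be streamed repeatedly, bit-identically,
without being held in memory.

Four scripted edge-case sequences reproduce the known failure modes of the
approach: entering the scene already falling (no reference can be
enrolled), falling at the frame border (tracking lost), leaving before
falling, and recovering faster than the evaluation window.

## Evaluation

Sequence verdicts aggregate into a 3-class confusion matrix (ADL / Fall /
Warning) with an extra bucket for sequences in which no person was ever
recognised. The two-class accuracy groups Fall and Warning into a single
positive class: `Ac(2) = 100 (TP + TN) / (TP + TN + FP + FN)`, with an
unrecognised sequence whose truth is positive counted as a false negative
and an unrecognised ADL excluded (it raises no alarm). The three-class
accuracy is the trace fraction over classified sequences. Both are
reported to one decimal.

Cross-validation is leave-one-actor-out: for each subject a classifier is
trained on all other subjects' frames (balanced, then standardised inside
the pipeline) and the full detector — rules plus that classifier — runs on
the held-out subject's sequences.
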