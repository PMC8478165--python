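"""Named analysis windows, in ms relative to the alignment event at 0.

All windows are half-open ``[start, end)``.  These are the canonical epochs of
the peri-saccadic complex-spike (CS) analysis:

* ``EARLY_POST`` — saccade-related burst period, from primary saccade offset.
* ``LATE_POST`` — error-related tonic period, from primary saccade offset.
* ``PRECORRECTIVE`` — error period preceding a corrective saccade, from its onset.
* ``POSTCORRECTIVE`` — corrective-saccade burst period, from corrective offset.
* ``TRIAL_ONSET_WIN`` — predictive response period, from trial onset
  (reappearance of the central fixation dot).
* ``REGRESSION_EARLY`` / ``REGRESSION_LATE`` — non-overlapping windows used by
  the per-cell amplitude/error multiple regression, from primary offset.
* ``RATE_BASELINE`` — pre-saccadic baseline used by the trough estimator,
  from primary saccade onset.
* ``DURATION_BASELINE`` — baseline for the CS-duration 3-SD epoch rule,
  from primary saccade onset.
"""

EARLY_POST = (0.0, 100.0)
LATE_POST = (50.0, 250.0)
PRECORRECTIVE = (-200.0, 0.0)
POSTCORRECTIVE = (0.0, 100.0)
TRIAL_ONSET_WIN = (150.0, 250.0)
REGRESSION_EARLY = (40.0, 80.0)
REGRESSION_LATE = (100.0, 250.0)
RATE_BASELINE = (-200.0, 0.0)
DURATION_BASELINE = (-200.0, -100.0)

#: alignment labels accepted throughout the package
ALIGNMENTS = (
    "saccade_onset",
    "saccade_offset",
    "corrective_onset",
    "corrective_offset",
    "trial_onset",
)
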