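"""Simulate a study-shaped cohort and look at one participant's recording.

Generates 41 paired wristband sessions + questionnaire rows with a latent
two-class emotion structure, then prints what one session looks like.
"""

from edaffect import SynthConfig, simulate_cohort

cohort = simulate_cohort(SynthConfig(seed=1))
session = cohort.sessions[0]

print(f"participants: {len(cohort.sessions)}")
print(f"{session.participant_id}: {len(session.samples)} samples at "
      f"{session.fs:g} Hz ({session.duration:.0f} s)")
print(f"markers (begin/end per exercise): {len(session.markers)}")
print(f"conductance range: {session.samples.min():.2f}-"
      f"{session.samples.max():.2f} uS")
n1 = sum(cohort.truth.labels.values())
print(f"latent classes: {len(cohort.truth) - n1} negative-dominant, "
      f"{n1} positive-dominant")
# The markers delimit the 60/10/10 s exercises; the class drives both the
# skin-conductance-response rate/amplitude and the questionnaire answers.
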