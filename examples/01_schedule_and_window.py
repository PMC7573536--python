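"""Build neurofeedback run schedules and inspect moving-window mixing.

The feedback value at each volume comes from a 20-volume moving window,
so windows near block boundaries mix feedback and no-feedback volumes.
This script prints the condition mixture across one feedback mini-block.
"""

from fcnf import build_run_schedule, window_composition

# standard design: 20-volume fixation, then 7 alternating pairs of
# 20-volume feedback (fcnf) and no-feedback (nonf) mini-blocks
schedule = build_run_schedule(20, 7, 20, 20, "fcnf")
print(f"run length: {schedule.n_volumes} volumes, "
      f"{len(schedule.mini_blocks())} mini-blocks after fixation")

print("\nwindow mixture across the first feedback mini-block (volumes 21-40):")
for t in (21, 22, 30, 40):
    comp = window_composition(schedule, t, L=20)
    print(f"  volume {t}: {comp.n_fcnf} feedback : "
          f"{comp.n_nonf + comp.n_fixation} other")

# the extended design lengthens feedback blocks to 40 volumes, so the
# window saturates at 20 feedback volumes for the second half of a block
extended = build_run_schedule(20, 5, 40, 20, "nonf")
print(f"\nextended design: {extended.n_volumes} volumes per run")

# Reading: the count climbs 1, 2, ..., 20 across a 20-volume feedback
# block — the feedback shown early in a block still reflects mostly
# no-feedback volumes, which is why per-position profiles matter.
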