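"""The three difficulty controllers reacting to a rising heart rate.

Drives each scenario's rule with avgHR sweeping 85 -> 105 bpm and prints how
the difficulty quantity moves: below 95 bpm the game hardens (faster
character, shorter countdown, more frequent blocks); at or above 95 bpm it
eases. Bounds are enforced throughout: countdown in [5, 15] s, generation
rate in [0.1, 1.83] blocks/s.
"""

from hradapt import (
    Scenario1State,
    Scenario2State,
    Scenario3State,
    step_scenario1,
    step_scenario2,
    step_scenario3,
)

print("scenario 1 (flying character): goal completions at w=0.3")
s1 = Scenario1State(d=6, deltaD=5, vh=10)
for hr in (88, 91, 99, 103):
    s1 = step_scenario1(s1, avg_hr=hr, w=0.3)
    print(f"  avgHR={hr:>3} -> speed vh={s1.vh:7.3f}, goal deltaD={s1.deltaD:7.3f}")

print("scenario 2 (bathtub countdown): one completed round per line")
s2 = Scenario2State()
for hr in (88, 90, 92, 99, 103):
    s2, _ = step_scenario2(s2, button_pressed=True, avg_hr=hr)
    print(f"  avgHR={hr:>3} -> allotted={s2.allotted:4.1f} s, points={s2.points}")

print("scenario 3 (falling blocks): one caught block per line")
s3 = Scenario3State()
for hr in (88, 90, 92, 99, 103):
    s3 = step_scenario3(s3, s_pressed=True, s_onscreen=True, avg_hr=hr)
    print(f"  avgHR={hr:>3} -> gen_rate={s3.gen_rate:.3f} blocks/s, points={s3.points}")

print()
print("Each rule pushes effort up while the child is below the 95 bpm target")
print("and backs off once the child is working at or above it.")
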