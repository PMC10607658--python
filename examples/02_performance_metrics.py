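"""Exercise-quality metrics from a behavioral action log.

A Puzzle log scores positioning accuracy A (mean placement deviation per
action, in percent of a normalized scene unit -- lower is better), and a
Shooting log scores reaction accuracy A = K/N * 100 (higher is better).
Both carry duration T = Tf - T0 and speed S = N/T, so S*T = N always.
"""

from vrphobia import ActionEvent, ActionLog, compute_performance

puzzle = ActionLog(
    scene_id=1, exercise="Puzzle", t_start=0.0, t_end=80.0,
    events=[
        ActionEvent(8.0 * (i + 1), "placement",
                    placed=(0.50 + 0.02 * i, 0.40, 0.30),
                    target=(0.50, 0.40, 0.30))
        for i in range(10)
    ],
)
m = compute_performance(puzzle)
print(f"Puzzle:   A={m.accuracy:.2f}% (lower is better: "
      f"{m.accuracy_lower_is_better}), T={m.duration:.1f}s, S={m.speed:.3f}/s")

shooting = ActionLog(
    scene_id=4, exercise="Shooting", t_start=0.0, t_end=25.0,
    events=[ActionEvent(2.0 * (i + 1), "shot", success=i % 3 != 2)
            for i in range(10)],
)
m = compute_performance(shooting)
print(f"Shooting: A={m.accuracy:.1f}% of shots hit, "
      f"T={m.duration:.1f}s, S={m.speed:.3f} actions/s")
# The Puzzle A sums placement deviations (here 0.02*(i) scene units per
# placement) over all 10 actions; the Shooting A is simply the hit rate.
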