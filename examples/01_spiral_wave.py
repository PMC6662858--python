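"""Stationary-rectangle FitzHugh-Nagumo spiral wave.

Runs the classic broken-front benchmark (depolarized lower-left quadrant,
refractory upper half) on the [0, 2.5]^2 tissue square embedded in the
[-0.1, 2.6]^2 ghost box, at a desk-scale resolution, and reports the
standard spiral observables.
"""

from gsmono.benchmarks import run_spiral_benchmark

# scale 0.25: 69x69 ghost box, dt = 0.4 -- forms the same spiral as the
# printed 275x275 resolution in under a minute
m = run_spiral_benchmark("rect_stationary", scale=0.25, t_end=1000.0)

print(f"grid {m.grid_n}x{m.grid_n}, dt={m.dt}, run to t={m.t_end:g}")
print(f"rotation sense (y up):   {m.rotation}")
print(f"rotation period:         {m.period:.1f} time units")
print(f"front speed at (1.5,1.5): {m.front_speed:.4f}  (normal speed from "
      "upstroke-delay gradients, late passes)")
print(f"arm width at t_end:      {m.arm_width:.3f}  (u >= 0.5 segment along "
      "the front normal near the centroid)")
print(f"excited fraction at end: {(m.final_snapshot >= 0.5).mean():.2f}")
# A clockwise rotating single arm with a stable period means the broken
# front has curled into a sustained reentrant spiral; the speed ~0.005 and
# width ~0.16 are the intrinsic front properties of the model at K = 1e-4.
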