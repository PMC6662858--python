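"""Healthy vs left-bundle-branch-block activation on the synthetic
transverse ventricular section.

Healthy mode stimulates the Purkinje-fed regions (septum plus the lower
endocardium of both ventricles) simultaneously; LBBB mode stimulates only
the right-ventricular endocardium, so the left ventricle must activate by
slow myocardial conduction across the septum.  Activation time = first
0 mV upstroke at each probe, measured from stimulus onset.
"""

from gsmono.ventricle import activation_comparison

runs = activation_comparison("transverse", dx=0.7, dt=0.5, t_end=1200.0)

names = runs["healthy"].probe_names
print(f"{'probe':>14} {'healthy (ms)':>13} {'LBBB (ms)':>10} {'delay':>8}")
for n in names:
    h = runs["healthy"].activation[n]
    l = runs["lbbb"].activation[n]
    print(f"{n:>14} {h:13.1f} {l:10.1f} {l - h:+8.1f}")
# Expected pattern: the septal probe (on the RV-facing septal surface) is
# stimulated directly in both modes and activates at the same time; the LV
# lateral wall, last in line for transseptal spread, is delayed by hundreds
# of ms under LBBB -- the hallmark of the conduction defect.
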