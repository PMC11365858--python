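"""Sweep the GM-SD scaling factor k and recover the generative optimum.

Generates a small phantom cohort whose T1 cores sit at a contrast of 1.7
effective GM SDs below the GM mean, re-segments every phantom at each k
in 1.0..2.0, and selects the k whose Youden cutpoints on T1 volume and
T1/T2% best separate the groups.  (The published sweep uses the same grid;
its optimum was k = 1.7.)
"""

from myelotype import kgrid_recovery_experiment

res = kgrid_recovery_experiment(n_per_group=8, seed=3)
df = res.to_frame()
print(df[["k", "t1vol_accuracy", "t1vol_cutoff",
          "ratio_accuracy", "ratio_cutoff"]].to_string(index=False,
                                                       float_format="%.3f"))
print(f"\nselected k: {res.selected_k}")
# Accuracy peaks near the generative core contrast: permissive k admit
# variable non-specific rim voxels, stringent k reduce core capture below
# the connected-component filter and both groups collapse toward zero.
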