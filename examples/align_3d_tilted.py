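"""3D alignment of randomly tilted flat rings.

Simulates flat 9-cluster rings tilted randomly within +/-60 degrees about
the x axis and spun within 360 degrees about z, then aligns them with the
tilt-search loop (no deformation) and checks the averaged projection for
ring symmetry.
"""

from ringalign.protocols import run_tilted_protocol_3d

run, curve = run_tilted_protocol_3d(seed=1, phi_range=72.0, phi_step=6.0,
                                    angle_step=3.0, n_iterations=5)

final_tilt_increments = [phi for phi, _ in run.history[-1]]
print(f"aligned structures        : {len(run.aligned)}")
print(f"final-iteration tilt steps: {final_tilt_increments}")
print(f"autocorr peaks            : "
      f"{[(round(a), round(h, 2)) for a, h in curve.peaks]}")
print()
print("Peaks near multiples of 40 deg show that the x-y projection of the")
print("averaged, de-tilted ensemble recovered the 9-fold cluster ring that")
print("was invisible in the average of the raw tilted structures.")
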