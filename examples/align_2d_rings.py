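"""Deformed 2D alignment of simulated under-labeled rings.

Simulates 20 ring structures (9 cluster sites, only 5 labeled per ring),
runs the deformed alignment pipeline, and reads the recovered symmetry off
the rotational autocorrelation of the averaged result.
"""

from ringalign.protocols import run_ring_protocol_2d

report = run_ring_protocol_2d("ring9-underlabeled", seed=1)

print(f"aligned structures : {len(report.result.aligned)}")
print(f"common radius R    : {report.result.radius:.1f} nm")
print(f"final mean NRMSE   : {report.result.run.mean_nrmse[-1]:.3f}")
print(f"autocorr peaks     : "
      f"{[(round(a), round(h, 2)) for a, h in report.autocorr.peaks]}")
print(f"dominant peak      : {report.dominant_angle:.0f} deg")
print()
print("A dominant peak at 40 deg is the signature of 9-fold symmetry")
print("(360/9 = 40): the alignment recovered the full ring arrangement even")
print("though each individual structure shows only 5 of its 9 clusters.")
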