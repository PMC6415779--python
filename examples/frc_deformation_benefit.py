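"""Does circularizing semi-flexible rings sharpen the average?

Simulates elliptically distorted rings (aspect ratio up to 1.35, the range
seen for real ciliary distal appendages), aligns them once with the
deformation step and once rigidly, and compares Fourier Ring Correlation
resolutions of the two averages.
"""

from ringalign.protocols import run_deformation_benefit

print("seed  deformed-FRC  rigid-FRC")
wins = 0
seeds = range(100, 108)
for seed in seeds:
    deformed, rigid = run_deformation_benefit(seed)
    wins += deformed < rigid
    print(f"{seed:4d}  {deformed:8.1f} nm  {rigid:7.1f} nm")
print(f"\ndeformed alignment finer in {wins}/{len(list(seeds))} replicates")
print("Smaller FRC resolution = sharper average: normalizing each ring's")
print("ellipse onto a common circle before rigid registration removes the")
print("shape heterogeneity that otherwise blurs the averaged clusters.")
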