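"""Sweep the regularization weight and score PSNR/SSIM against the truth.

Reconstructs the same simulated study at several lambda values. Moderate
regularization beats both the unregularized solution (which fits noise)
and heavy regularization (which cannot leave the IAA initialization).
"""

import srrmri as s
from srrmri.transforms import RigidTransform
from srrmri.volumes import VoxelGrid

grid = VoxelGrid((64, 64, 64), (0.5, 0.5, 0.5))
_, truth, _ = s.make_phantom(s.PhantomSpec(grid=grid, geometry_seed=0, noise_sd=0.0))
specs = [s.AcquisitionSpec.for_hr_grid(grid, ax, 2.0) for ax in "xyz"]
scans = s.simulate_acquisitions(truth, specs, None, s.NoiseModel(sd=10.0, seed=0))
ident = [RigidTransform()] * 3

rows = s.lambda_sweep(
    scans, specs, ident, truth,
    lambdas=[0.0, 0.01, 0.05, 0.1, 0.3, 1.0],
    config=s.SolverConfig(max_iters=20),
)
print(f"{'lambda':>7} {'PSNR dB':>8} {'SSIM':>6} {'iters':>5}")
for r in rows:
    print(f"{r['lambda']:7.2f} {r['psnr_db']:8.2f} {r['ssim']:6.3f} {r['iterations']:5d}")
best = max(rows, key=lambda r: r["psnr_db"])
print(f"best lambda: {best['lambda']} ({best['psnr_db']:.2f} dB)")
# -> the curve peaks at a strictly positive lambda: the gradient guidance
#    carries real information beyond the data term.
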