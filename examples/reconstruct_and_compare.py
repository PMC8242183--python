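"""Fuse three orthogonal stacks into an isotropic volume; compare baselines.

Reconstructs with gradient-guidance SRR (lambda = 0.1), the TV prior, the
single-image (n=1) configuration, and plain interpolate-and-average, then
scores each against the known ground truth.
"""

import srrmri as s
from srrmri.guidance import iaa_combine
from srrmri.srr_solver import interpolate_scans_to_hr
from srrmri.transforms import RigidTransform
from srrmri.volumes import VoxelGrid

grid = VoxelGrid((64, 64, 64), (0.5, 0.5, 0.5))
_, truth, _ = s.make_phantom(s.PhantomSpec(grid=grid, geometry_seed=0, noise_sd=0.0))
specs = [s.AcquisitionSpec.for_hr_grid(grid, ax, 2.0) for ax in "xyz"]
scans = s.simulate_acquisitions(truth, specs, None, s.NoiseModel(sd=10.0, seed=0))
ident = [RigidTransform()] * 3

recons = {}
recons["iaa"] = iaa_combine(interpolate_scans_to_hr(scans, specs, ident))
recons["srr"], trace = s.srr_reconstruct(
    scans, specs, ident, s.SolverConfig(lam=0.1, max_iters=25)
)
recons["tv"], _ = s.srr_reconstruct(
    scans, specs, ident, s.SolverConfig(lam=0.1, max_iters=25, mode="tv")
)
# SISR: one stack with 3x more slices (matched phase-encode budget)
sisr_spec = s.AcquisitionSpec("z", 2.0 / 3.0, specs[2].inplane_spacing, 48, grid)
sisr_scan = s.simulate_acquisitions(truth, [sisr_spec], None, s.NoiseModel(10.0, 0))
recons["sisr"], _ = s.srr_reconstruct(
    sisr_scan, [sisr_spec], None, s.SolverConfig(lam=0.1, max_iters=25)
)

print(f"SRR objective fell {trace.total[0]:.3g} -> {trace.total[-1]:.3g} "
      f"over {len(trace) - 1} accepted iterations (never increases)")
print(f"{'method':>6} {'PSNR dB':>8} {'SSIM':>6}")
for name, rec in recons.items():
    print(f"{name:>6} {s.psnr(rec, truth):8.2f} {s.ssim(rec, truth):6.3f}")
# -> SRR outscores IAA by several dB: deconvolution restores the resolution
#    that averaging blurs away, while the L1 guidance suppresses the noise.
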