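"""Quantify image quality: partial-volume effect, SNR and CNR.

Fits the 3-component Gaussian mixture to a reconstruction's intensity
histogram, derives FWHM pure-tissue intervals, and reports the percentage
of mixed (partial-volume) voxels plus SNR/CNR in dB against background
noise.
"""

import srrmri as s
from srrmri.transforms import RigidTransform
from srrmri.guidance import iaa_combine
from srrmri.srr_solver import interpolate_scans_to_hr
from srrmri.volumes import VoxelGrid

grid = VoxelGrid((64, 64, 64), (0.5, 0.5, 0.5))
_, truth, _ = s.make_phantom(s.PhantomSpec(grid=grid, geometry_seed=0, noise_sd=0.0))
specs = [s.AcquisitionSpec.for_hr_grid(grid, ax, 2.0) for ax in "xyz"]
scans = s.simulate_acquisitions(truth, specs, None, s.NoiseModel(sd=10.0, seed=0))
ident = [RigidTransform()] * 3

iaa = iaa_combine(interpolate_scans_to_hr(scans, specs, ident))
srr, _ = s.srr_reconstruct(scans, specs, ident, s.SolverConfig(lam=0.1, max_iters=25))

for name, vol in (("IAA", iaa), ("SRR", srr)):
    rep = s.assess_volume(vol, contrast="t2", reference=truth)
    print(f"{name}: PVE {rep.pve_percent:5.2f}%  SNR {rep.snr_db:5.2f} dB  "
          f"CNR CSF-GM {rep.cnr_csf_gm:5.2f}  CSF-WM {rep.cnr_csf_wm:5.2f}  "
          f"GM-WM {rep.cnr_gm_wm:5.2f} dB  (PSNR {rep.psnr_db:.2f} dB)")
# -> lower PVE means fewer voxels mixing tissues, i.e. higher effective
#    spatial resolution; SNR/CNR are measured against corner background noise.
# Caveat: even pure Gaussian classes leave ~23.9% of draws outside their
# FWHM interval, so PVE is a comparative metric, not an absolute fraction.
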