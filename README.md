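# memdot

Maximum Entropy on the Mean (MEM) reconstruction for functional
near-infrared spectroscopy (fNIRS) diffuse optical tomography, with
depth-weighted minimum-norm estimation (MNE) as the reference method, a
fully synthetic validation phantom, and the spatial/temporal metrics used
to score surface reconstructions.

## The problem

fNIRS measures optical-density changes ΔOD between scalp sources and
detectors; tomography inverts the linear model

    Y = A X + e

for the cortical absorption changes `X` (vertices × time), where `A` is the
light-sensitivity matrix (channels × vertices) and `e` is physiological
noise.  The problem is severely ill-posed and biased toward superficial
cortex because optical sensitivity decays roughly exponentially with depth.

Two solvers are implemented:

* **Depth-weighted MNE** — the Tikhonov/MAP solution
  `X = (AᵀΣ_d A + λ (ΛΛᵀ)⁻¹)⁻¹ AᵀΣ_d Y` with
  `diag(Λ) = diag(AᵀΣ_d A)^(−ω)`; `ω = 0` is plain MNE, `ω = 0.5` is
  standard depth weighting.  λ is chosen by L-curve corner or Morozov
  discrepancy.
* **MEM** — among all source distributions whose mean explains the data,
  pick the one closest in relative entropy to a reference prior that
  factorizes over K data-driven cortical parcels, each a Bernoulli–Gaussian
  mixture `(1−α_k) δ(x_k) + α_k N(0, Σ_k(t))`.  The Dirac component lets
  inactive parcels *switch off*, which is why MEM recovers spatial extent
  where MNE smears.  The problem reduces to maximizing the concave
  channel-space dual `D(λ) = λᵀy − F_ν(Aᵀλ) − ½ λᵀΣ_noise λ`, and the
  estimate is the free-energy gradient at `ξ = Aᵀλ*`.  Depth weighting
  enters via two exponents: ω₂ for the depth-weighted MNE whose locally
  normalized energy scales each `Σ_k(t)`, and ω₁ for the per-parcel depth
  scaling — the combination is written `MEM(ω₁, ω₂)`.

Because no public forward model or recordings accompany the method, the
package ships a synthetic phantom: a folded hemispheric cortex (depth
5–35 mm), the full double-density optode montage (8 sources, 10 detectors,
50 channels at 0.7/1.5/3.0/3.35 cm), an analytic banana-path sensitivity
model, and a resting-state-like noise generator with systemic physiology —
plus the 250-seed × 4-extent × 4-SNR factorial simulation design and the
four validation metrics (AUC, Dmin, SD, SE).

## Worked example

```python
from memdot.pipeline import RunConfig, run_experiment
from memdot.simulate import GridConfig

cfg = RunConfig(
    grid=GridConfig(n_superficial=5, n_middle=0, n_deep=0,
                    extents=(5,), snrs=(5.0,)),
    methods=("MEM(0.3,0.5)", "MNE(0.5)"),
)
df, summary = run_experiment(cfg)
print(df.groupby("method")[["auc", "dmin_mm", "sd_mm", "se"]].median())
```

prints (medians over 5 superficial trials at SNR 5):

```
                   auc  dmin_mm      sd_mm        se
method
MEM(0.3,0.5)  0.968929      0.0  22.981683  0.187162
MNE(0.5)      0.975996      0.0  37.133600  0.076729
```

Both solvers put the reconstruction peak inside the simulated generator
(`dmin_mm = 0`) with high discrimination (AUC near 1); MEM spreads far
less around the true generator (SD 23 vs 37 mm), while MNE's smoother
maps track the time course marginally better (smaller SE) — the
qualitative signature of the two methods.  The `examples/` scripts walk
through each capability (phantom, simulation, reconstruction, grid study,
preprocessing + hemoglobin unmixing) with commented output.

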