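# cardio-unload

Passive myocardial material parameters and the unloaded (stress-free)
reference configuration of the left ventricle, estimated simultaneously
from a single loaded geometry and one measured end-diastolic
pressure-volume pair.

## The problem

Image-based cardiac mechanics models need two things that clinical data do
not provide directly: a stress-free reference geometry (images show the
ventricle under end-diastolic pressure, `p_ed`) and patient-specific
passive stiffness parameters. Both are entangled — the reference shape
depends on the material, and any fit of the material depends on the
reference shape. This package solves the coupled inverse problem with a
fixed-point scheme:

1. **Target EDPVR.** From the measured pair `(p_ed, V_ed)` the single-beat
   empirical end-diastolic pressure-volume relation is constructed: an
   unloaded volume `V0 = V_ed (0.6 - 0.006 P_ed[mmHg])` and a power law
   `p = alpha V^beta` through the measured point (any other sampled
   PV-curve can serve as the target instead).
2. **Unloading.** A backward-displacement iteration recovers the reference
   coordinates: inflate the current candidate `X^k` to `p_ed`, compare with
   the imaged coordinates, subtract the mismatch —
   `X^{k+1} = X^k - l*beta*R^k` — with Aitken delta-squared acceleration of
   `beta` and an Armijo-style backtracking line search on `l` that damps
   unfavourable updates.
3. **Parameter rescaling.** After each unloading step the exponential
   model function `Phi(x, x0) = a/(2b) (exp(b (x - x0)/x0) - 1)` is fitted
   (Levenberg-Marquardt) independently to the target curve and to the
   simulated loading curve; all stress-like parameters `a_(.)` are
   multiplied by `a_fit_target / a_fit_sim` and all exponents `b_(.)` by
   `b_fit_target / |b_fit_sim|` (clamped to `[1/5, 5]`).

Geometry and parameters converge together, typically within ~10-13
iterations, i.e. at the cost of only a handful of passive-inflation
simulations. A Nelder-Mead cost-functional baseline (which pays one full
unloading per cost evaluation) is included for verification.

The forward model is total-Lagrangian finite elasticity on linear
tetrahedra with an element-constant volumetric penalty, follower pressure
on the endocardium, spring boundary conditions at the base and apex, and a
library of myocardial constitutive laws (Demiray, Guccione, Usyk, and
Holzapfel-Ogden variants with fiber dispersion) with literature default
parameters. Patient meshes are not distributable, so an idealized
truncated-ellipsoid LV generator with rule-based transmural fibers stands
in; see `docs/methods.md` for the model details and limitations.

## Worked example

```python
from cardio_unload import (EllipsoidSpec, PassiveLVModel, SolverConfig,
                           generate_synthetic_case)

# a synthetic "patient": a known unloaded ventricle inflated to 1.07 kPa
case = generate_synthetic_case(EllipsoidSpec(resolution=10.0),
                               true_scalings=(0.35, 0.60), p_ed=1.07,
                               solver_config=SolverConfig(n_ls=30))

model = PassiveLVModel(case.x_dat, p_ed=case.p_ed, V_ed=case.V_ed,
                       model_id="reduced_HO",
                       solver_config=SolverConfig(n_ls=30))
res = model.fit(max_iter=40)      # fits the single-beat empirical EDPVR
print(res.summary())
```

prints (abridged):

```
Passive LV inverse fit
====================================================
constitutive law:     reduced_HO
measured PV-pair:     p_ed = 1.070 kPa, V_ed = 140.94 mL
target EDPVR:         single-beat empirical (V0 = 77.78 mL)
method:               MFF (fixed point)
fitted scalings:      a_scale = 0.1747, b_scale = 0.4614
unloaded volume V0:   78.29 mL
iterations:           13 (16 forward solves)
goodness of fit:      r_V0,rel = 0.367 %V_ed, r_An,rel = 5.72 %A_klotz
max nodal error:      0.0114 mm
converged:            True
parameters:
    a      = 0.1413 kPa
    a_f    = 0.3338 kPa
    ...
```

Reading this: the empirical EDPVR predicts an unloaded volume of 77.8 mL;
the fit finds a reference configuration whose cavity volume matches it to
0.37% of `V_ed` while reproducing the curve's shape to ~6% in normalized
area, and ends with literature stiffness parameters scaled down to 17%
(stress-like) and 46% (exponents) — ex vivo parameter sets are
systematically too stiff for in vivo behaviour, so scalings well below one
are the expected outcome. `res.history_frame()` returns the per-iteration
diagnostics; `res.validate()` re-inflates the fitted unloaded mesh with a
fully converging Newton and reports the goodness of fit of that validation
curve.

The same pipeline is scriptable from the shell:

```bash
cardio-unload synth --seed 1 --out case/          # synthetic patient
cardio-unload mff --mesh case/loaded.vtk --ped 1.07 --out fit/
cardio-unload pipeline --out run/                 # synth -> fit -> validate
cardio-unload sensitivity --axis init             # robustness study
```

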