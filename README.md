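# flextail

Integrative modeling of a flexible, charged protein tail on a rigid
repeat-protein core — and the binding assays that go with it.

Chaperone-GEF proteins of the armadillo-repeat family carry disordered
C-terminal tails that fold back onto the core domain and are essential for
stability and nucleotide-exchange activity, but they are invisible to
crystallography.  `flextail` re-implements, at desk scale, the workflow
used to model such tails: crosslinking mass spectrometry (XL-MS) yields
lysine-pair distance restraints (DSS chemistry: spacer 11.4 Å + two Lys
side chains ≈ 24 Å Cα-Cα reach, <30 Å working threshold); a restrained
two-stage Monte Carlo sampler generates candidate tail conformations; each
candidate is scored against small-angle X-ray scattering by the Debye
equation and a χ² fit with analytic scale; and a selection cascade — energy
ranking, χ² < 2.0, held-out crosslink satisfaction, RMSD leader clustering
with minor-cluster rejection — picks representative models.  The same
package fits the accompanying solution measurements: 1:1 biolayer
interferometry kinetics (k_obs = k_a·C + k_d, K_D = mean k_d / mean k_a),
steady-state one-site binding, differential-scanning-fluorimetry melting
temperatures, one-phase association, plus structural metrics
(solvent-accessible surface area and interface burial, Cα distances,
ensemble RMSF).

The restraint penalty is the flat-harmonic

    f(d) = 0                           d ≤ x0 + tol        (30 Å at defaults)
    f(d) = ((d − x0 − tol)/σ)²         otherwise

and every stage of the pipeline is testable without downloads through a
synthetic-data module that builds a solenoid core with a basic surface
patch, grows a charged tail with known ("truth") conformation, and
simulates crosslinks, SEC-SAXS frames, BLI traces and melt curves with
known parameters.

## Worked example

```python
import numpy as np
from flextail.kinetics import combine_kinetics, fit_association, fit_dissociation
from flextail.synthetic import NoiseSpec, simulate_bli
from flextail.xlms import max_linker_distance

# 1:1 binding traces at four analyte concentrations, 1% noise
concs = np.array([0.25, 0.5, 1.0, 2.0]) * 1e-6
tt = simulate_bli(k_a=1.3e5, k_d=0.031, Bmax=1.0, concentrations=concs,
                  noise=NoiseSpec(trace_sd=0.01, seed=0))
kas, kds = [], []
for ci, C in enumerate(concs):
    t, y = tt.t, tt.signals[f"conc_{ci}"]
    assoc = t <= tt.metadata["t_assoc"]
    kd = fit_dissociation((t[~assoc], y[~assoc])).k_d
    kas.append(fit_association((t[assoc], y[assoc]), C, kd).k_a)
    kds.append(kd)
rc = combine_kinetics(kas, kds)
print(f"k_a = {rc.k_a:.3g} /M/s   k_d = {rc.k_d:.3g} /s   "
      f"K_D = {rc.K_D*1e6:.2f} uM")
print(f"DSS max Ca-Ca reach: {max_linker_distance():.1f} A")
```

prints

```
k_a = 1.3e+05 /M/s   k_d = 0.0311 /s   K_D = 0.24 uM
DSS max Ca-Ca reach: 24.2 A
```

the association and dissociation rate constants recovered from the noisy
traces, their mean-rate equilibrium constant (0.24 µM — sub-micromolar,
i.e. high-affinity binding), and the crosslinker's geometric reach.

The full structural pipeline runs with

```python
from flextail.pipeline import run_pipeline
res = run_pipeline(seed=0, n_models=200)
print(res.stage_counts, res.representative_rmsd)
```

which generates the synthetic truth system, samples 200 restrained tail
conformations, filters them through the cascade and reports the selected
representative together with its tail-RMSD to the known truth.

A small CLI covers the crosslink utilities:

```bash
flextail xl-report --model model.pdb --links links.csv --threshold 30
flextail xl-fdr --matches matches.csv --copies 10 --fdr 0.05
```

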