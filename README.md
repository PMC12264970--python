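# rbfebench

Analysis toolkit for nonequilibrium **relative binding free energy
(RBFE)** benchmarks — for computational chemists who run fast-switching
alchemical calculations and want to connect their accuracy to the
quality of the starting structures.

Given forward (λ: 0→1) and reverse (λ: 1→0) switching work values, the
package estimates ΔG per thermodynamic-cycle leg with the
Crooks-fluctuation-theorem maximum-likelihood (Bennett acceptance ratio)
estimator: ΔG solves

    Σᵢ [1 + exp(β(M + W_F,i − ΔG))]⁻¹ = Σⱼ [1 + exp(−β(M − W_R,j − ΔG))]⁻¹,

with β = 1/kT and M = kT ln(n_F/n_R). Per-pair ΔΔG = ΔG(protein leg) −
ΔG(water leg) (or directly from combined double-system-single-box
works), averaged over replicas, with a standard error from a two-step
bootstrap: resample works → ΔG_b; redraw from Normal(ΔG, SD(ΔG_b)); pool
across replicas; SE(leg) = √(var(pool)/n_replica); combine legs in
quadrature.

On the benchmark side it computes the statistics that relate error to
structure quality: unsigned error UE = |ΔΔG_calc − ΔΔG_exp| and AUE with
bootstrap SEs, consensus / best-set / affinity / data-source splits,
Pearson matrices of UE against structural features (resolution, ligand
and pocket B-factors, binding-site water count), linear UE-vs-resolution
fits with ±0.1 Å binning, nominal resolutions for predicted structures,
ΔΔG sign accuracy, and crystal-water placement scoring (1 Å cutoff,
optimal one-to-one matching). Seeded synthetic generators produce every
input class with known ground truth, so the whole pipeline is testable
without MD or downloads.

## Worked example

```python
import rbfebench as rb
from rbfebench.uncertainty import ddg_with_uncertainty
from rbfebench.units import KT_298

# three replicas of 80+80 Crooks-consistent works per leg,
# true ΔΔG = 10 − 3 = 7 kJ/mol = 1.673 kcal/mol
prot = [rb.gen_work_distributions(
            rb.WorkGenSpec(dg_true=10.0, sigma_w=2*KT_298, seed=10+r),
            leg="protein", replica_id=r) for r in range(3)]
wat  = [rb.gen_work_distributions(
            rb.WorkGenSpec(dg_true=3.0, sigma_w=2*KT_298, seed=15+r),
            leg="water", replica_id=r) for r in range(3)]

est = ddg_with_uncertainty(prot, wat,
                           rb.BootstrapConfig(n_boot=1000, n_replica=3, seed=7))
print(f"ddG = {est.ddg:.3f} ± {est.se:.3f} kcal/mol")
```

prints

```
ddG = 1.746 ± 0.143 kcal/mol
```

— the replica-averaged estimate sits half a standard error from the true
1.673 kcal/mol, and the SE is the four-step bootstrap propagation
(per-leg work resampling → Normal redraw → replica pooling → quadrature).

The `examples/` directory holds one narrative script per capability
(ΔΔG estimation, bootstrap uncertainty, water-placement scoring,
structure features, benchmark analysis); each prints its numbers with a
line on what they mean. A thin CLI mirrors the stages:

```bash
rbfebench simulate --kind benchmark --out bench.csv --seed 4 --n-pairs 50
rbfebench analyze bench.csv --split affinity --fit --nominal-aue 1.9
rbfebench waters reference.pdb predicted.pdb --matching optimal
```

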