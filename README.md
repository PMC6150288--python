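# fepkit

A desk-scale toolkit for alchemical free-energy perturbation (FEP)
calculations: staged transformation planning, Zwanzig free-energy estimation
with replica and hysteresis diagnostics, thermodynamic-cycle algebra for
relative binding free energies, and water-occupancy hydration-site mapping.
It is aimed at computational chemists and structural bioinformaticians who
want to prototype, teach, or validate FEP protocols — the staging logic, the
estimators, and the cycle bookkeeping — without running a molecular-dynamics
engine: all sampling comes from built-in analytic test systems with known
closed-form answers, or from energy-difference samples you supply as CSV.

## The method

FEP computes a free-energy difference between two states by exponential
averaging (Zwanzig) of potential-energy differences sampled in one state:

    ΔG = −kT · ln ⟨ exp(−ΔU / kT) ⟩

evaluated per λ-window along a coupling path from the initial (λ = 0) to the
final (λ = 1) Hamiltonian and summed over windows.  Because a single leg is
rarely informative on its own, legs are combined through thermodynamic
cycles into relative binding free energies ΔΔG:

* **ligand perturbation** — transform ligand 1 into ligand 2 in the bound
  and in the water-solvated state: ΔΔG = ΔG_bound − ΔG_solvent;
* **in-silico mutagenesis** — annihilate a sidechain to alanine in the
  ligand–receptor complex and in the apo receptor:
  ΔΔG = ΔG_complex − ΔG_apo, directly comparable to
  RT·ln(K_D,mutant / K_D,WT) from binding assays; non-alanine mutations join
  two reduction cycles through a common fragment;
* **conformational selectivity** — run the same ligand perturbation against
  the active-like and inactive receptor conformations; the difference of the
  two ΔΔG values reports which ligand prefers the active state.

Large perturbations are staged: partial charges are removed first, van der
Waals interactions are converted to soft-core form, the charge group is
annihilated, and the charges of the final species are restored — applied
charge group by charge group, starting with the group topologically farthest
from the anchor atom (Cα for sidechains).  Each stage is sampled along
uniformly spaced λ-windows (21 per stage for sidechains, 51 for ligands),
with 10 independent replicas providing the standard error of the mean and
the forward/backward discrepancy (hysteresis) serving as the convergence
diagnostic.

The hydration module bins water-oxygen positions from trajectory frames onto
a 1 Å grid; a voxel's occupancy is the fraction of frames containing a water
oxygen, and connected clusters above 80 % occupancy are reported as
conserved hydration sites.

## Worked example

Plan the staged annihilation of an asparagine sidechain to alanine:

```text
$ fepkit plan --mutation N254A
# sidechain plan N254A, 21 lambda-windows/stage
step  stage       charge_group      lambda
   0  decharge    amide             0.00 -> 1.00 (21 windows, spacing 0.05)
   1  softcore    amide             0.00 -> 1.00 (21 windows, spacing 0.05)
   2  annihilate  amide             0.00 -> 1.00 (21 windows, spacing 0.05)
   3  decharge    carbonyl          0.00 -> 1.00 (21 windows, spacing 0.05)
   4  softcore    carbonyl          0.00 -> 1.00 (21 windows, spacing 0.05)
   5  annihilate  carbonyl          0.00 -> 1.00 (21 windows, spacing 0.05)
   6  recharge    end_state         0.00 -> 1.00 (21 windows, spacing 0.05)
```

The amide nitrogen group (farthest from Cα) is annihilated before the
carbonyl group, and a single recharge stage restores the end-state charges.

Sample a validation system — a 1-D harmonic oscillator whose force constant
changes from 1 to 4 kcal/(mol·Å²) — with the full sidechain protocol, and
estimate the leg free energy:

```text
$ fepkit simulate --ka 1 --kb 4 --windows 21 --steps 10000 --replicas 10 \
      --seed 7 --out leg.csv
$ fepkit estimate --samples leg.csv
dG = 0.4116 +/- 0.0007 kcal/mol (hysteresis 0.0009, n=10)
```

The classical partition-function ratio gives the exact answer
(kT/2)·ln 4 = 0.4105 kcal/mol at 298 K, so the Monte-Carlo estimate is
within two standard errors of the truth, with sub-0.001 kcal/mol hysteresis.

The same estimators accept any energy CSV in the documented dialect
(columns `replica, stage, window_index, lambda_from, lambda_to, direction,
dU_kcal_mol, temperature_K`, one sample per row), and `fepkit report` runs a
whole manifest of mutation or ligand cycles into a results JSON plus a
calculated-vs-experimental comparison table.

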