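# aslreg

Arterial spin labeling (ASL) MRI measures cerebral blood flow (CBF)
without contrast, but its value for detecting regional hypoperfusion —
for example the frontal and temporal patterns seen across the
frontotemporal lobar degeneration (FTLD) spectrum — hinges on how
accurately the low-resolution perfusion image is aligned to the
participant's structural T1-weighted image. `aslreg` is a simulation and
evaluation toolkit for exactly that question. It implements:

* a **synthetic cohort generator**: digital head phantoms with an analytic
  gray/white-matter boundary surface, a forward pCASL acquisition model
  (14 label–control pairs, 28 volumes, separate M0), known ground-truth
  rigid ASL→T1w transforms, group-level regional hypoperfusion, and a
  clinical-severity covariate coupled to CBF;
* **CBF quantification** via the single-compartment pCASL kinetic model

      CBF = 6000 λ ΔM exp(PLD/T1b) / (2 α T1b M0 (1 − exp(−τ/T1b)))

  with motion correction, control−label subtraction, and time-series
  averaging;
* a **QEI-style quality gate** (maps pass iff QEI > 0.4);
* three **registration strategies**: emulated manual alignment,
  FLIRT-like rigid intensity registration (correlation ratio, multiscale
  Powell), and boundary-based registration (BBR) refining either
  initialization against the GM–WM boundary contrast of the CBF map;
* a **registration-consistency framework**: vertex-wise pairwise Pearson
  correlations between participants' surface-projected CBF maps, mean
  participant CC, and paired/two-sample method comparisons;
* **ROI statistics** on a 219-parcel cortical parcellation: two-tailed
  two-sample t-tests with Bonferroni family-wise control for
  hypoperfusion and atrophy, per-ROI CBF–severity linear regression, and
  demographic tests.

Because every phantom's transform, CBF map, and regional effect are known
by construction, each stage is testable against ground truth — recovery of
poses to sub-voxel accuracy, exactness of the kinetic round trip, nominal
family-wise error rates, and the expected ranking of registration methods
by inter-subject consistency.

## Worked example

Run a small end-to-end experiment — simulate a three-group cohort,
quantify, QC-gate, register with all three methods, project to the
surface, and evaluate consistency:

```python
import aslreg as ar

spec = ar.PhantomSpec(
    structural_shape=(48, 48, 40), structural_spacing=(2.5, 2.5, 2.5),
    asl_shape=(40, 40, 24), asl_spacing=(3.75, 3.75, 3.75),
    noise_sd=1.0, seed=7,
)
effects = [
    ar.GroupEffectSpec(group="tau_like", affected_rois=(3, 4, 5),
                       cbf_reduction_fraction=0.25,
                       severity_slope=-1.5, severity_noise_sd=2.0),
    ar.GroupEffectSpec(group="tdp_like", affected_rois=(10, 11, 12),
                       cbf_reduction_fraction=0.25,
                       severity_slope=-1.5, severity_noise_sd=2.0),
]
config = ar.ExperimentConfig(
    n_per_group={"control": 5, "tau_like": 4, "tdp_like": 4},
    effects=effects, phantom=spec, seed=11,
)
report = ar.run_experiment(config)
print(report.mean_cc.groupby("method")["mean_cc"].mean())
```

prints

```
method
FLIRT+BBR     0.377083
manual        0.271942
manual+BBR    0.376694
Name: mean_cc, dtype: float64
```

— the emulated manual registration (operator error 1 mm/1° per axis) is
less consistent across participants than either BBR-refined method, and
the two BBR variants agree to three decimals, which is the qualitative
signature of boundary-based refinement: it converges to the same alignment
whether initialized from a manual or an automated rigid registration.
`report` also carries the pairwise-CC tables, method and group
comparisons, per-ROI hypoperfusion tests (Bonferroni-corrected over 219
parcels), severity regressions, and QEI/registration exclusion accounting.

The same pipeline is available stage-by-stage from the command line
(`aslreg simulate | quantify | qc | register | project | evaluate-cc |
group-stats | run-all`), reading and writing NIfTI volumes, plain-text
transforms and surfaces, and TSV tables in a BIDS-inspired layout.

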