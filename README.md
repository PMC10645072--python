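# reesfit

Red edge excitation shift (REES) analysis of intrinsic tryptophan
fluorescence, built for comparing the structural dynamics of closely
related proteins — the motivating case is a panel of IgG3 antibody Fc
allotypes in which an Arg292Trp polymorphism changes the tryptophan
count from 22 to 24 per molecule and visibly shifts the REES signature.

REES exploits the fact that exciting tryptophan at progressively longer
("red edge") wavelengths photo-selects sub-populations whose solvent
shells have not relaxed, so the emission spectrum red-shifts with
excitation wavelength. How strongly it shifts reports on solvent
exposure and the rigidity of the Trp microenvironments.

## What the package computes

1. **Centre of spectral mass (CSM)** of each emission spectrum over a
   closed window (default 325–500 nm):

   CSM = Σᵢ fᵢ·λ_Em,i / Σᵢ fᵢ

   computed per excitation wavelength (default 292–310 nm, 1 nm steps)
   to give one CSM profile per replicate (`reesfit.csm`).

2. **Two-state sigmoidal thermodynamic model** fitted to each profile:

   CSM(λ_Ex) = [CSM(λ_ExFC) + CSM(λ_ExR)·e^x] / (1 + e^x),
   x = m·(λ_Ex − λ_Ex50%)/(R·T)

   where CSM(λ_ExFC) is the Franck–Condon (blue) asymptote, CSM(λ_ExR)
   the fully solvent-relaxed (red) asymptote, λ_Ex50% the inflection and
   m (reported as ΔG_m, J mol⁻¹ nm⁻¹) the slope term read as structural
   rigidity. CSM(λ_ExR) is not experimentally reachable, so it is fitted
   **globally** — one shared value for all replicates of all samples in
   a group with equal Trp content, bound-constrained to [387, 440] nm —
   while (CSM(λ_ExFC), m, λ_Ex50%) stay free per replicate
   (`reesfit.model`).

3. **Per-tryptophan solvent-accessible surface area** from PDB models
   via an implemented Shrake–Rupley algorithm with deterministic
   point sets (probe 1.4 Å, 960 points), reporting absolute SASA,
   relative exposure (% of a maximal-exposure reference, default
   264 Å²) and the average SASA per Trp (`reesfit.sasa`).

4. **Group statistics**: one-way ANOVA with Tukey HSD post hoc
   comparisons of REES parameters between groups, and Pearson
   correlations of CSM(λ_ExFC) and ΔG_m against average SASA per Trp
   (`reesfit.stats`).

5. **A forward simulator** that generates excitation–emission matrices
   whose CSM profiles follow the sigmoid exactly (band centres are
   solved so the window-truncated discrete CSM hits the model value),
   with the two-group / triplicate design used for all recovery tests
   (`reesfit.synthetic`).

The published per-allele REES summary for the 21 IgG3 variants ships as
a packaged table (`reesfit.datasets`).

## Worked example

Simulate a study-scale cohort (18 samples with 22 Trp, 3 with 24 Trp,
triplicates, 0.1 nm CSM noise), extract CSM profiles, and fit each group
globally:

```python
from reesfit import fit_group_global
from reesfit.csm import build_profile
from reesfit.synthetic import study_cohort_spec, simulate_cohort

spec = study_cohort_spec(seed=11)
scans, truth = simulate_cohort(spec)
profiles = [build_profile(scan) for scan in scans]

by_group = {}
for p in profiles:
    by_group.setdefault(p.group_label, []).append(p)

for label, group_profiles in by_group.items():
    result = fit_group_global(group_profiles)
    fc = result.per_sample_summary["csm_fc_avg"]
    print(f"{label}: {len(group_profiles)} profiles, "
          f"CSM(lExFc) group mean {fc.mean():.1f} nm, "
          f"shared CSM(lExR) {result.shared_csm_r:.1f} +/- {result.shared_csm_r_se:.1f} nm")
```

prints

```
IgG3-Arg292: 54 profiles, CSM(lExFc) group mean 352.9 nm, shared CSM(lExR) 411.2 +/- 6.0 nm
IgG3-Trp292: 9 profiles, CSM(lExFc) group mean 353.8 nm, shared CSM(lExR) 394.6 +/- 11.2 nm
```

The Franck–Condon asymptotes are recovered at the generating values
(352.9 vs 353.9 nm — the 24-Trp group sits a nanometre redder because
its extra tryptophans are solvent exposed). The relaxed-state CSM is an
extrapolation ~80 nm beyond the measurable excitation range and carries
accordingly large uncertainty; the shared-parameter global fit is what
keeps it identifiable at all.

The packaged reference table reproduces the published group summaries
and correlations:

```
$ rees reference-table
             n_alleles  csm_fc_mean  csm_fc_sd  dgm_mean  dgm_sd  csm_r  sasa_per_trp_mean  sasa_per_trp_sd
group
IgG3-Arg292         18     352.9222     0.2819       7.0  0.2142  418.9             8.0106           1.8255
IgG3-Trp292          3     353.9333     0.2517       7.8  0.1732  423.3            18.8067           2.7061
csm_fc_vs_sasa: r = 0.7383 (p = 1.33e-04, n = 21)
dgm_vs_sasa: r = 0.7072 (p = 3.37e-04, n = 21)
```

i.e. the 24-Trp group has a redder Franck–Condon CSM, a steeper slope
term and more than double the average SASA per tryptophan, and both
REES parameters correlate positively (r ≈ 0.7) with solvent exposure.

A full pipeline run (`rees run --config run.json`) chains ingest → CSM →
global fit → SASA → statistics and writes per-stage CSVs plus a
versioned JSON report; `rees simulate`, `rees csm`, `rees fit`,
`rees sasa` and `rees compare` expose the individual stages.

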