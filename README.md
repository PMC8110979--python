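# airwaymorph

3D cephalometric morphometry of the pediatric upper airway, built around
the screening question: which skeletal features of **mandibular
hypoplasia** (Pierre–Robin sequence, Treacher–Collins, Goldenhar,
hemifacial microsomia) predict a **difficult airway** — difficult facemask
ventilation or difficult tracheal intubation — before an anesthetist ever
touches the patient?

The package is written for anesthesiologists, craniofacial surgeons and
imaging scientists who digitize anatomical landmarks from head CT and want
a reproducible pipeline from raw landmark tables to screening statistics.

## What it computes

1. **Reference frame** (`airwaymorph.geometry`).  The averaged Frankfort
   horizontal plane is built from Orbitale L/R and Porion L/R by excluding
   each point in turn, fitting the four three-point planes, sign-aligning
   and averaging their normals.  The midsagittal plane passes through
   Nasion and Opisthion perpendicular to it; the coronal plane through the
   posterior vomer point perpendicular to both.  Every scan is reoriented
   into the canonical frame (+x right, +y anterior, +z superior).

2. **Measurements** (`airwaymorph.measure`, `airwaymorph.specs`).  A
   declarative bundle of distances, angles, perpendicular offsets and
   plane-bounded mesh regions: hyoid anterior/posterior distances (HAD,
   HPD), ramus height/width, body length/width, gonial angle, bigonial
   distance, the **inferior pogonial angle** (IPA: Go–Pog–Go), tongue
   offsets, and nasopharynx/oropharynx/hypopharynx/oral-cavity volumes and
   midsagittal areas.

3. **Normative growth and Δ scores** (`airwaymorph.normative`).  Control
   growth is modelled as a power law, `ln v = α + β ln(age)`, fitted by
   OLS per measurement.  A subject's deviation score is
   `Δ = exp(α + β ln age) − v_observed`: positive for dimensions that fall
   short of the age-expected normal, negative for angles wider than
   expected.

4. **Screening statistics** (`airwaymorph.screening`).  Normality-gated
   group tests (Welch t / Mann–Whitney U), crude and age/sex-adjusted
   logistic regression with Wald OR intervals, ROC analysis of Δ scores
   with Youden-index cutoffs and DeLong confidence intervals, and the
   logistic combination of ΔIPA + ΔHAD into a single screening score.

5. **Reliability** (`airwaymorph.reliability`).  Bland–Altman agreement of
   two observers on landmark-to-origin distances plus the 3D landmark
   placement error.

6. **Synthetic cohort** (`airwaymorph.simulate`).  A fully parametric
   generator of two demographically matched cohorts (default 42 + 42) with
   power-law growth, group deficits, ~2 mm inter-observer landmark noise,
   closed airway meshes with analytically known compartment volumes, and
   difficult-airway labels drawn from a logistic model on the true IPA and
   HAD.  Every analysis stage is testable against the generator's latent
   truth without any imaging data.

## Worked example

The `analysis/` scripts run the whole study on the synthetic cohort
(seed 7).  `python analysis/01_simulate_cohort.py` through
`05_reliability.py` print, among other things:

```
wrote 84 subjects to .../results/cohort
difficult airways: 8 of 84 (9.5% prevalence)

delta-IPA: AUC 0.933 (95% CI 0.878-0.987), cutoff -7.8 deg (less),
           sens 1.00 spec 0.87
combined delta-IPA + delta-HAD: AUC 0.926

720 pairs from 40 scans: bias -0.043 mm, LoA [-2.55, 2.46] mm
  landmark error [hypoplasia]: 1.98 ± 0.81 mm (n=360)
  landmark error [control]:    2.07 ± 0.85 mm (n=360)
```

Reading: subjects whose inferior pogonial angle is ≥ 7.8° wider than the
control growth curve predicts for their age (Δ ≤ −7.8°) are flagged; on
this cohort that rule catches every difficult airway while keeping 87% of
the easy airways unflagged.  The two simulated observers disagree by about
2 mm per landmark with no systematic bias — the level of digitization
noise the whole pipeline is designed to tolerate.

The same stages are available as a CLI
(`airwaymorph simulate|measure|fit-normative|screen|reliability|report`)
and as one orchestrated run (`analysis/06_full_report.py`), which also
writes dentition-stratified comparison tables (≤ 5 vs > 5 years).

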