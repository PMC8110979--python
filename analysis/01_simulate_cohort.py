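#!/usr/bin/env python
"""Generate the synthetic two-cohort study (42 mandibular-hypoplasia and 42
matched control subjects, two observers each) and write its landmark,
demographics and latent-truth files under results/cohort/."""
from pathlib import Path

from airwaymorph.simulate import GrowthConfig, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 7


def main() -> None:
    cohort = generate_cohort(GrowthConfig(), n_per_group=42, seed=SEED)
    cohort.write(OUT)
    demo = cohort.demographics()
    print(f"wrote {len(cohort.subjects)} subjects to {OUT}")
    print(demo.groupby("group")[["age_months"]].median().round(1))
    print("difficult airways:", int(demo["difficult_airway"].sum()),
          f"of {len(demo)} "
          f"({demo['difficult_airway'].mean():.1%} prevalence)")


if __name__ == "__main__":
    main()
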