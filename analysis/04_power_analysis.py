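"""Power analysis of PE comparisons and the sample-mass recommendation.

All-pairs arcsine two-proportion power tests within each nominal-mass group
(4,950 pairs per group), target-zone summaries (power >= 0.8 and
|PE_i - PE_j| <= 0.25), best/worst-case minimum-detectable-difference
curves, and the minimum pod mass needed to detect a 0.25 PE difference.
"""

from pathlib import Path

import pandas as pd

from seedpe.power import (
    PowerTestSpec,
    min_detectable_difference,
    pairwise_power_analysis,
    plan_sample_mass,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    traits = pd.read_csv(OUT / "traits.csv")
    spec = PowerTestSpec(alpha=0.05, target_power=0.8, max_diff=0.25)

    pairs, groups = pairwise_power_analysis(traits, spec)
    pairs.to_csv(OUT / "power_pairs.csv", index=False)
    groups.to_csv(OUT / "power_groups.csv", index=False)
    frac_overall = (pairs["power"] >= 0.8).mean()
    print(f"{len(pairs)} pairwise tests; {frac_overall:.1%} reach 80% power overall")
    print(groups.round(3).to_string(index=False))

    print("\ntheoretical minimum detectable PE difference (80% power):")
    for n, label in ((46, "1 g (~46 objects)"), (92, "2 g (~92 objects)")):
        worst = min_detectable_difference(n, 0.5, spec)
        best = min_detectable_difference(n, 0.85, spec)
        print(f"  {label}: worst case {worst:.3f}, best case {best:.3f}")

    opg = round(traits["nopgs"].mean())
    plan = plan_sample_mass(objects_per_gram=opg, target_diff=0.25,
                            center=0.5, spec=spec)
    plan.per_gram.to_csv(OUT / "power_plan.csv", index=False)
    plan.curve.to_frame().to_csv(OUT / "power_curve_worst.csv", index=False)
    plan_sample_mass(opg, 0.25, 0.85, spec).curve.to_frame().to_csv(
        OUT / "power_curve_best.csv", index=False
    )
    print(f"\nat {opg} objects/g, minimum sample mass to detect a 0.25 PE "
          f"difference: {plan.recommended_grams} g")


if __name__ == "__main__":
    main()
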