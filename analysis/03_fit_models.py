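"""Fit the statistical models over the trait table.

Count GLM with Gaussian vs Poisson link compared on a 20% holdout
(RMSE/MAE), sequential ANOVA, Bland-Altman agreement between observed and
GLM-predicted totals, binomial-logit proportion models with LRT /
Hosmer-Lemeshow / Nagelkerke diagnostics, estimated marginal means with
adjusted pairwise contrasts, variance-component repeatability of the PE
traits, TWGSS dispersion of (NOPGS, NOPGM) by method, and the trait PCA.
Writes one CSV per analysis under results/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from seedpe.stats import (
    anova_type1,
    bland_altman,
    emm_pairwise,
    estimate_variance_components,
    fit_proportion_model,
    hosmer_lemeshow,
    pca_biplot,
    repeatability,
    select_count_model,
    twgss,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SPLIT_SEED = 7


def main() -> None:
    warnings.simplefilter("ignore")
    traits = pd.read_csv(OUT / "traits.csv")

    # --- total-object count model: link comparison on a holdout ----------
    holdout = np.random.default_rng(SPLIT_SEED).random(len(traits)) < 0.2
    fit, comparison = select_count_model(traits, holdout)
    comparison.to_csv(OUT / "count_model_links.csv", index=False)
    print(f"count model: selected {fit.link} "
          f"(holdout RMSE {fit.rmse:.2f}, MAE {fit.mae:.2f})")
    anova = anova_type1(traits).reset_index(names="term")
    anova.to_csv(OUT / "count_model_anova.csv", index=False)
    print("ANOVA p-values:",
          {r["term"]: float(f"{r['PR(>F)']:.3g}") for _, r in anova.iterrows()
           if pd.notna(r["PR(>F)"])})

    mean_d, lo, hi = bland_altman(traits["total_objects"], fit.fitted)
    pd.DataFrame(
        {"mean_difference": [mean_d], "lower_limit": [lo], "upper_limit": [hi]}
    ).to_csv(OUT / "bland_altman.csv", index=False)
    print(f"Bland-Altman: mean diff {mean_d:.3f}, limits [{lo:.2f}, {hi:.2f}]")

    # --- proportion GLMs --------------------------------------------------
    rows = []
    for resp in ("p_ip", "p_ws", "p_ss", "pe"):
        pfit = fit_proportion_model(traits, resp)
        succ = traits[resp] * traits["total_objects"]
        chi2, df, hl_p = hosmer_lemeshow(
            succ, traits["total_objects"], np.clip(pfit.fitted, 1e-9, 1 - 1e-9)
        )
        rows.append(
            {
                "response": resp,
                "lrt_p": pfit.extra["lrt_p"],
                "hosmer_lemeshow_p": hl_p,
                "nagelkerke_r2": pfit.extra["nagelkerke_r2"],
                "separation": pfit.extra["separation"],
            }
        )
        if resp == "p_ip":
            emm, contrasts = emm_pairwise(pfit, traits, "variety")
            emm.to_csv(OUT / "emm_p_ip_variety.csv", index=False)
            contrasts.to_csv(OUT / "contrasts_p_ip_variety.csv", index=False)
    prop = pd.DataFrame(rows)
    prop.to_csv(OUT / "proportion_models.csv", index=False)
    print("proportion models:")
    print(prop.round(4).to_string(index=False))

    # --- repeatability of the PE traits -----------------------------------
    tr = traits.copy()
    tr["environment"] = (
        tr["processing_method"] + ":" + tr["nominal_mass_g"].astype(str)
    )
    rep_rows = []
    for trait_name in ("pe", "pe_ws", "pe_ss"):
        vc = estimate_variance_components(tr, trait_name, "variety", "environment")
        rep_rows.append({"trait": trait_name, "repeatability": repeatability(vc),
                         "sigma2_g": vc.sigma2_g, "sigma2_resid": vc.sigma2_resid})
    rep = pd.DataFrame(rep_rows)
    rep.to_csv(OUT / "repeatability.csv", index=False)
    print("repeatability:", {r["trait"]: round(r["repeatability"], 4) for r in rep_rows})

    # --- clustering dispersion and PCA ------------------------------------
    tw = [
        {"processing_method": m,
         "twgss": twgss(g[["nopgs", "nopgm"]].to_numpy(), g["variety"].to_numpy())}
        for m, g in traits.groupby("processing_method")
    ]
    pd.DataFrame(tw).to_csv(OUT / "twgss.csv", index=False)
    print("TWGSS by method:", {d["processing_method"]: round(d["twgss"], 1) for d in tw})

    pca = pca_biplot(
        traits[["p_ip", "p_ws", "p_ss", "pe", "pe_ws", "pe_ss",
                "nopgs", "nopgm", "total_objects"]]
    )
    pca.loadings.reset_index(names="trait").to_csv(OUT / "pca_loadings.csv", index=False)
    print(f"PCA: first two components explain "
          f"{pca.variance_explained[:2].sum():.1%} of the variance")


if __name__ == "__main__":
    main()
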