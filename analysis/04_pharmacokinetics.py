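#!/usr/bin/env python
"""Pharmacokinetic study: decay-model fits, F-test selection, NCA parameters.

Fits each antibody x dose arm with one- and two-compartment decay models,
selects between them with the extra sum-of-squares F-test (falling back to
mono-exponential when LOQ censoring leaves too few points), and derives
C0, terminal half-life, AUC(0-144 h), CL, MRT and V_D,ss.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from abframe.pk import nca, select_decay_model
from abframe.simulate import GeneratorConfig, generate_pk_study


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--t-end", type=float, default=144.0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = generate_pk_study(GeneratorConfig(seed=args.seed))
    rows = []
    for (antibody, dose), data in study.items():
        fit, selection = select_decay_model(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # truncated-AUC notice for censored arms
            params = nca(data, fit, t_end=args.t_end)
        rows.append({
            "antibody": antibody, "dose_mg_per_kg": dose, "model": fit.model,
            "n_uncensored": data.n_uncensored_points,
            "c0_mg_per_l": params.c0_mg_per_l,
            "t_half_beta_h": params.t_half_beta_h,
            "auc_mg_h_per_l": params.auc_mg_h_per_l,
            "cl_ml_per_h_per_kg": params.cl_ml_per_h_per_kg,
            "mrt_h": params.mrt_h, "vdss_ml_per_kg": params.vdss_ml_per_kg,
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "pk_parameters.tsv", sep="\t", index=False)
    print(table.round(2).to_string(index=False))

    both = table.set_index(["antibody", "dose_mg_per_kg"])
    auc_ratio = (both.loc[("9-EIVLGE", 30.0), "auc_mg_h_per_l"]
                 / both.loc[("2-DIQMAQ-K", 30.0), "auc_mg_h_per_l"])
    print(f"\nexposure ratio (optimized / parental) at 30 mg/kg: {auc_ratio:.1f}x")
    opt = table[table.antibody == "9-EIVLGE"]["t_half_beta_h"].mean() / 24
    print(f"dose-averaged terminal half-life, optimized variant: {opt:.1f} days")


if __name__ == "__main__":
    main()
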