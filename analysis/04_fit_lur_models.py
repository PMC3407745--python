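"""Fit the two period-specific land use regression models: site annual means,
then sign-constrained backward stepwise elimination on log concentrations."""

import argparse

from citylur.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    res = run_pipeline(PipelineConfig(seed=args.seed), args.out, last_stage="fit-lur")
    for tag in ("model1", "model2"):
        m = res[tag]
        print(f"\n{tag} (campaign {m.campaign}, {m.n_sites} sites): "
              f"adjusted R^2 = {m.adjusted_r2:.3f}, log-scale RMSE = {m.rmse_log:.3f}")
        for name in m.predictors:
            print(f"  {name:22s} {m.coefficients[name]: .7f}   p = {m.pvalues[name]:.3f}")
        removed = [t["removed"] for t in m.removal_trace]
        print(f"  eliminated: {', '.join(removed) if removed else 'none'}")


if __name__ == "__main__":
    main()
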