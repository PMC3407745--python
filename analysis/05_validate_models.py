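"""Validate both exposure models: leave-one-out cross-validation on the
concentration scale, variance inflation factors, Cook's distance and Moran's I
of residuals (permutation test)."""

import argparse

from citylur.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    res = run_pipeline(PipelineConfig(seed=args.seed), args.out, last_stage="validate")
    for tag, v in res["validation"].items():
        print(f"\n{tag}:")
        print(f"  LOOCV: R^2 = {v['cv_r2']:.2f}, adjusted R^2 = {v['cv_adjusted_r2']:.2f}, "
              f"RMSE = {v['cv_rmse']:.2f} ug/m3")
        if "vif_mean" in v:
            print(f"  mean VIF = {v['vif_mean']:.2f} (max {max(v['vif'].values()):.2f})")
        print(f"  max Cook's D = {v['cooks_max']:.3f}; flagged sites: {v['cooks_flagged'] or 'none'}")
        print(f"  Moran's I = {v['moran_I']:.3f}, permutation p = {v['moran_p']:.3f}")


if __name__ == "__main__":
    main()
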