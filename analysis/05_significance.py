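"""Significance of the feature differences between the pair sets.

Assembles the descriptive-statistics table (N, mean, SD per set) with the
ratio-resampling p-value per contrast, runs the overall Fisher test on the
proportion of multi-site pairs, and the per-family Fisher tests for the
selected families. Ends by rendering the plain-text run report.
"""
import pandas as pd
from _common import default_config

from mirfeat.pipeline import stage_report, stage_stats


def main() -> None:
    cfg = default_config()
    table1 = stage_stats(cfg)

    print("Descriptive statistics and ratio-test p-values:")
    print(table1.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print()
    fisher = pd.read_csv(cfg.output_dir / "fisher_overall.tsv", sep="\t")
    row = fisher.iloc[0]
    sel_frac = row.selected_multi / (row.selected_multi + row.selected_single)
    bg_frac = row.background_multi / (row.background_multi + row.background_single)
    print(f"multi-site pairs: selected {row.selected_multi}/"
          f"{row.selected_multi + row.selected_single} ({sel_frac:.3f}) vs "
          f"background {row.background_multi}/"
          f"{row.background_multi + row.background_single} ({bg_frac:.3f}); "
          f"Fisher p = {row.p:.3g}")
    per_fam = pd.read_csv(cfg.output_dir / "fisher_per_family.tsv", sep="\t")
    n_sig = int((per_fam["p"] < cfg.alpha).sum())
    print(f"per-family Fisher: {n_sig} of {len(per_fam)} selected families "
          f"significant at alpha={cfg.alpha}")
    report = stage_report(cfg)
    print(f"report written to {report}")


if __name__ == "__main__":
    main()
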