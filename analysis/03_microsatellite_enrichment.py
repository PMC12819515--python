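#!/usr/bin/env python
"""GGAA microsatellite enrichment in super-enhancers vs typical enhancers.

Counts GGAA/TTCC tandem runs (>= 4 consecutive copies) per region,
normalizes per kb, compares per-sample SE vs enhancer means with a paired
Wilcoxon signed-rank test, and reports the fraction of regions containing
any microsatellite. Writes per-sample statistics to results/run/.
"""

from pathlib import Path

import pandas as pd

from secrc.pipeline import PipelineConfig, load_study, stage_se_calling, stage_msat

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = load_study(PipelineConfig(dataset_dir=str(ROOT / "results" / "dataset")))
    profiles = stage_se_calling(study)
    msat = stage_msat(study, profiles)
    out = ROOT / "results" / "run"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "sample_id": study.case_ids,
        "se_mean_per_kb": msat["se_means"],
        "enhancer_mean_per_kb": msat["enhancer_means"],
    }).to_csv(out / "msat_stats.tsv", sep="\t", index=False)
    print(f"mean mSat density per kb: SE={sum(msat['se_means'])/len(msat['se_means']):.3f} "
          f"enhancer={sum(msat['enhancer_means'])/len(msat['enhancer_means']):.3f}")
    print(f"paired Wilcoxon (n={msat['n_pairs']}): p={msat['wilcoxon_p']:.2e}")
    print(f"regions with >= 1 mSat: SEs {msat['pct_se_with_msat']:.1f}% "
          f"vs enhancers {msat['pct_enhancer_with_msat']:.1f}%")


if __name__ == "__main__":
    main()
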