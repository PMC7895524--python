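"""Validate the released crowns against scene truth and field surveys.

Three analyses, pooled over the campaign sites:

1. crown precision/recall at IoU > 0.5, with and without the 3 m LiDAR
   filter — the difference is the filter's contribution;
2. exclusive stem recall against overstory-selected field stems;
3. the mixed-model height validation (field height ~ predicted height
   with a site random intercept, REML), reporting the conditional RMSE
   and the mean signed bias.

Writes results/validation_metrics.json and prints the headline numbers.

Usage: python analysis/03_validate_predictions.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from crownscape import campaign


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    runs = campaign.run_campaign(args.seed)
    cm = campaign.crown_metrics(runs)
    sm = campaign.stem_metrics(runs)
    hm = campaign.height_metrics(runs)

    print(
        f"crown matching (IoU > 0.5, {cm['n_predictions']} predictions vs "
        f"{cm['n_references']} truth crowns):"
    )
    print(f"  precision {cm['precision']:.1%}, recall {cm['recall']:.1%}")
    print(
        f"  3 m LiDAR filter effect: precision {cm['filter_precision_gain']:+.1%}, "
        f"recall {cm['filter_recall_change']:+.1%}"
    )
    print(
        f"stem recall: {sm['stem_recall']:.1%} "
        f"({sm['n_matched']}/{sm['n_overstory_stems']} overstory field stems matched)"
    )
    print(
        f"height validation ({hm.n_pairs} pairs, {hm.n_sites} sites): "
        f"RMSE {hm.rmse_m:.2f} m, mean bias {hm.mean_bias_m:+.2f} m "
        f"(positive = predictions taller, as expected from the survey lag), "
        f"slope {hm.slope:.3f}"
    )

    args.out.mkdir(parents=True, exist_ok=True)
    metrics = {**{k: v for k, v in cm.items()}, **sm, **hm.__dict__}
    (args.out / "validation_metrics.json").write_text(
        json.dumps(metrics, indent=1, default=str) + "\n"
    )
    print(f"metrics written to {args.out / 'validation_metrics.json'}")


if __name__ == "__main__":
    main()
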