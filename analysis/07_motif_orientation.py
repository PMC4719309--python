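"""Orientation of the GA-repeat motif relative to host-gene transcription.

Generates peaks forced into introns and coding exons (100 each, planted
with opposing orientation biases), finds the best motif hit per peak, and
tests each feature class's +/− counts with an exact binomial test. Also
reports the feature-class fold enrichment of the default peak set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args

from roxevol.motif import PWM
from roxevol.regulatory_context import feature_assignment, orientation_bias
from roxevol.synthetic_data import PeakPlan, generate_chirp_experiment


def main() -> None:
    args = parse_args(__doc__)
    plan = PeakPlan(
        n_peaks={}, ppt_proximal_fraction=0.0,
        feature_peaks={"chrX": {"intron": 100, "CDS": 100}},
    )
    oriented = generate_chirp_experiment(
        {"chrX": 300_000}, {"chrX": "A"}, plan, seed=args.seed
    )
    pwm = PWM.from_instances([PeakPlan().mre_consensus])
    result = orientation_bias(
        oriented.peaks, pwm, oriented.gene_models, oriented.genome
    )
    result.counts.to_csv(args.out / "07_orientation_bias.tsv", sep="\t",
                         index=False)
    for _, row in result.counts.set_index("feature").loc[["intron", "CDS"]] \
            .reset_index().iterrows():
        print(f"{row['feature']}: {row['n_forward']} forward / "
              f"{row['n_reverse']} reverse (binomial p = {row['p_value']:.2g})")

    lengths = {"chrX": 300_000, "chr2": 100_000}
    default = generate_chirp_experiment(
        lengths, {"chrX": "A", "chr2": "B"}, PeakPlan(), seed=args.seed
    )
    features = feature_assignment(default.peaks, default.gene_models, lengths)
    features.to_csv(args.out / "07_feature_enrichment.tsv", sep="\t", index=False)
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
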