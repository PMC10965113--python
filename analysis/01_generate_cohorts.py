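#!/usr/bin/env python
"""Generate the synthetic cohorts every downstream analysis consumes.

Writes, under scratch/cohorts/ (bulky per-sample files, regenerated on
demand): a 10,000-sample blood cohort (bimodal mixture: 75% imprinted,
22.8% non-methylated, 2% intermediate, 0.2% over-methylated) with its
truth table and coupled expression vector, plus 500-sample cohorts for
each tissue preset that departs from blood's bimodality (skeletal muscle,
cerebellum, breast, prostate, testis).
"""

from pathlib import Path

from nc886.io import write_beta_matrix
from nc886.synthetic_data import PRESETS, generate_cohort, make_config

SEED = 886
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    config = make_config("blood")
    matrix, truth, expr = generate_cohort(config, 10_000, seed=SEED)
    write_beta_matrix(matrix, OUT / "blood_betas.tsv")
    truth.to_csv(OUT / "blood_truth.tsv", sep="\t")
    expr.to_csv(OUT / "blood_expression.tsv", sep="\t", header=True)
    print(f"blood: 10,000 samples; true category counts:")
    print(truth["true_category"].value_counts().to_string())

    for preset in sorted(PRESETS):
        if preset == "blood":
            continue
        m, t, _ = generate_cohort(make_config(preset), 500, seed=SEED)
        write_beta_matrix(m, OUT / f"{preset}_betas.tsv")
        t.to_csv(OUT / f"{preset}_truth.tsv", sep="\t")
        med = m.values.median(axis=0)
        print(f"{preset}: 500 samples, summary-beta median {med.median():.3f}")


if __name__ == "__main__":
    main()
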