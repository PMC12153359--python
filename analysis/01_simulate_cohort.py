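#!/usr/bin/env python
"""Simulate the survey-scale cohort: 405 strains x 76 viruses with two
planted pairwise dependencies (one co-occurrence, one incompatibility) and
single-spore-style lineages for the five most heavily co-infected strains.

Writes results/data/{matrix.csv, truth.csv, lineages.csv}.
"""

from pathlib import Path

import pandas as pd

from virorules import LineageConfig, SyntheticConfig, generate_lineages, generate_planted_matrix
from virorules.experiments import default_planted_pairs
from virorules.matrix_io import write_lineages, write_presence_matrix

OUT = Path("results/data")
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pairs = default_planted_pairs()
    syn = SyntheticConfig(seed=SEED, planted_pairs=tuple(pairs))
    matrix, truth = generate_planted_matrix(syn)
    write_presence_matrix(matrix, OUT / "matrix.csv")
    pd.DataFrame([t.__dict__ for t in truth]).to_csv(OUT / "truth.csv", index=False)

    lcfg = LineageConfig(retention_prob=0.8, n_offspring=10, seed=SEED + 1)
    top = matrix.strain_virus_counts().sort_values(ascending=False).index[:5]
    lineages = [
        generate_lineages(sid, matrix.data.columns[matrix.data.loc[sid] == 1], lcfg)
        for sid in top
    ]
    write_lineages(lineages, OUT / "lineages.csv")

    print(f"cohort: {matrix.n_strains} strains x {matrix.n_viruses} viruses -> {OUT}/matrix.csv")
    for t in truth:
        print(f"planted: {t.a} -> {t.b}  P(B|A)={t.p_b_given_a}  P(B|not A)={t.p_b_given_not_a}")
    print(f"lineages for {len(lineages)} parents ({lcfg.n_offspring} offspring each) "
          f"-> {OUT}/lineages.csv")


if __name__ == "__main__":
    main()
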