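#!/usr/bin/env python
"""Summarize the simulated cohort: per-virus prevalence and the co-infection
burden histogram (0 / 1 / 2 / 3-5 / 6-10 / 11-15 / 16-20 / 21+ viruses per
strain).

Reads results/data/matrix.csv; writes results/summary/*.csv.
"""

from pathlib import Path

from virorules import cohort_summary, read_presence_matrix

OUT = Path("results/summary")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = read_presence_matrix("results/data/matrix.csv")
    summary = cohort_summary(matrix)
    viruses, strains, hist = summary.to_frames()
    viruses.to_csv(OUT / "virus_prevalence.csv", index=False)
    strains.to_csv(OUT / "strain_burden.csv", index=False)
    hist.to_csv(OUT / "burden_histogram.csv", index=False)

    n = matrix.n_strains
    print(f"{n} strains, {matrix.n_viruses} viruses")
    print("co-infection burden histogram (viruses per strain):")
    for b, c in summary.histogram.items():
        print(f"  {b:>5}: {c:3d} strains ({100 * c / n:.1f}%)")
    top = summary.virus_counts.sort_values(ascending=False).head(3)
    print("most prevalent viruses:", ", ".join(f"{v} ({c})" for v, c in top.items()))


if __name__ == "__main__":
    main()
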