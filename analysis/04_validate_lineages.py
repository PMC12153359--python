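#!/usr/bin/env python
"""Validate the significant rules against the simulated lineages: for each
parent, screen the rules whose viruses the parent carries (predicted), test
each on every offspring under material implication, and report
predicted / confirmed / accuracy per rule form — the tabular twin of a
parent-offspring verification table.

Reads results/rules/significant.csv and results/data/lineages.csv; writes
results/validation/*.csv.
"""

from pathlib import Path

from virorules import read_lineages, summarize_validation
from virorules.matrix_io import read_rules_table

OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rules = read_rules_table("results/rules/significant.csv")
    lineages = read_lineages("results/data/lineages.csv")
    per_lineage, overall = summarize_validation(rules, lineages)
    per_lineage.to_csv(OUT / "per_lineage.csv", index=False)
    overall.to_csv(OUT / "overall.csv", index=False)

    print(f"{len(rules)} significant rules vs {len(lineages)} lineages")
    print(per_lineage.to_string(index=False))
    print("\npooled accuracy by rule form:")
    print(overall.to_string(index=False))


if __name__ == "__main__":
    main()
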