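#!/usr/bin/env python
"""Classify species into functional groups and summarize their diversity.

Each species is assigned to every combination of its foraging modes,
habitat categories and activity periods (24 possible groups); mixed
strategies therefore produce multi-group membership. The summary reports
group sizes, per-family functional diversity, unoccupied groups, and the
correlation between a family's species richness and the number of
functional groups it occupies.

Reads results/data/ecology.csv, writes results/group_assignment.csv and
results/group_summary.json.
"""

import json
from pathlib import Path

from phyloniche import classify, group_summary, read_ecology_table
from phyloniche.groups import write_group_assignment

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    eco = read_ecology_table(ROOT / "data" / "ecology.csv")
    ga = classify(eco)
    write_group_assignment(ga, ROOT / "group_assignment.csv")
    summary = group_summary(ga)
    (ROOT / "group_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    sizes = ga.group_sizes().sort_values(ascending=False)
    top = sizes.index[0]
    print(f"{summary['n_species']} species occupy "
          f"{summary['n_groups_represented']}/24 functional groups")
    print(f"most diverse group: {top} with {sizes.iloc[0]} species, "
          f"{summary['per_group'][top]['n_families']} families")
    print(f"species in more than one group: {summary['n_multi_group_species']} "
          f"({100 * summary['n_multi_group_species'] / summary['n_species']:.0f}%)")
    corr = summary["richness_group_correlation"]
    print(f"family richness vs. group count: r = {corr['r']:.2f} "
          f"(p = {corr['p_value']:.2g})")
    if summary["unrepresented_groups"]:
        print(f"unoccupied groups: {', '.join(summary['unrepresented_groups'])}")


if __name__ == "__main__":
    main()
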