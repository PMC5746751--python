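#!/usr/bin/env python
"""Classify the 16-system reference survey with the six-threshold voter.

Applies the gel/Ld threshold classifier to the packaged property table of
CmTMA+/CnS- bilayers (m, n in {10, 12, 14, 16}), checks the result against
the composition rule (gel iff both chains >= 12 carbons), and tabulates the
per-phase property extrema that motivate the threshold values.

Writes results/reference_classification.tsv and
results/reference_extrema.json.
"""

import json
from pathlib import Path

from ipabilayer import build_report, load_reference_table, records_from_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = load_reference_table()
    report, extrema = build_report(records_from_table(table))

    report.to_csv(OUT / "reference_classification.tsv", sep="\t", index=False)
    (OUT / "reference_extrema.json").write_text(json.dumps(extrema, indent=2))

    n_ok = int(report["agrees"].sum())
    print(f"{n_ok}/{len(report)} systems classified consistently with the "
          "composition rule (gel iff min(m, n) >= 12)")
    dissent = report[
        report[[c for c in report.columns if c.startswith("vote_")]]
        .apply(lambda r: len(set(r.dropna())) > 1, axis=1)
    ]
    for _, row in dissent.iterrows():
        minority = [
            c.removeprefix("vote_")
            for c in report.columns
            if c.startswith("vote_") and row[c] != row["overall"]
        ]
        print(f"  {row['abbreviation']}: minority votes from {minority} "
              f"(overall {row['overall']})")
    print("per-phase extrema (the thresholds sit between the groups):")
    for phase, stats in extrema.items():
        print(f"  {phase}: a_ipa [{stats['min_a_ipa']:.3f}, "
              f"{stats['max_a_ipa']:.3f}] nm^2, "
              f"K_A [{stats['min_k_a']:.0f}, {stats['max_k_a']:.0f}] mN/m")


if __name__ == "__main__":
    main()
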