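#!/usr/bin/env python
"""Target-site duplications, truncation sidedness and insertion relics.

Searches the flanks of every called element for the duplicated entrance-
sequence copy, classifies on which side the copy is truncated (5'-only at
the single-insertion locus; both sides for the tandem-insertion copies),
and scans element terminators for a poly-A + partial-palindrome relic (the
addax secondary-insertion footprint).  Writes results/tsd.tsv and
results/relics.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from palinsert.annotate import count_tandem_copies, decompose, orient_element
from palinsert.detect import call_panel
from palinsert.panel import build_panel, default_panel_config
from palinsert.tsd import classify_truncation, detect_relic, find_tsd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    panel = build_panel(default_panel_config(args.seed))
    calls = call_panel(panel)
    tsd_rows, relic_rows = [], []
    for sp in sorted(calls):
        for call in calls[sp]:
            rec = panel.by_name(sp)
            ori = orient_element(call.inserted_sequence, panel.element)
            comp = decompose(call.inserted_sequence, panel.element, ori.orientation)
            tandem = count_tandem_copies(
                call.inserted_sequence, panel.element,
                [panel.pali1, panel.pali2], ori.orientation,
            )
            at_is1 = abs(call.ref_position - panel.config.is1) <= 5
            n = len(call.inserted_sequence)
            if ori.orientation == "reverse":
                elem_hi = call.query_start + n - min(lo for lo, _ in tandem.copy_intervals)
            else:
                elem_hi = call.query_start + max(hi for _, hi in tandem.copy_intervals)
            flank5 = rec.sequence[max(0, call.query_start - 30) : call.query_start]
            flank3 = rec.sequence[elem_hi : elem_hi + 30]
            tsd = find_tsd(flank5, flank3)
            if tsd:
                trunc = classify_truncation(
                    tsd.duplicated_sequence,
                    panel.pali1 if at_is1 else panel.pali2,
                    allele=None if at_is1 else "eland",
                )
                tsd_rows.append(
                    {
                        "species": sp,
                        "duplicated_sequence": tsd.duplicated_sequence,
                        "match_length": tsd.match_length,
                        "truncated_5prime": trunc.truncated_5prime,
                        "truncated_3prime": trunc.truncated_3prime,
                    }
                )
            relic = detect_relic(comp, [panel.pali1, panel.pali2])
            if relic:
                relic_rows.append(
                    {
                        "species": sp,
                        "polya_length": relic.polya_interval[1] - relic.polya_interval[0],
                        "partial_template": relic.template_name,
                        "partial_length": relic.matched_length,
                        "between_repeats": (
                            f"{relic.terminator_repeats_before}|"
                            f"{relic.terminator_repeats_after}"
                        ),
                    }
                )
    args.out.mkdir(parents=True, exist_ok=True)
    tdf = pd.DataFrame(tsd_rows)
    rdf = pd.DataFrame(relic_rows)
    tdf.to_csv(args.out / "tsd.tsv", sep="\t", index=False)
    rdf.to_csv(args.out / "relics.tsv", sep="\t", index=False)
    print(tdf.to_string(index=False))
    print()
    print(rdf.to_string(index=False) if len(rdf) else "no relics detected")


if __name__ == "__main__":
    main()
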