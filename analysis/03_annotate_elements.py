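#!/usr/bin/env python
"""Decompose the called insertions: orientation, components, copies, variants.

For every called insertion: infer strand by local alignment against the
consensus element, locate monomers/linker/terminator, count tandem copies
(with the internal truncated-palindrome evidence that separates two adjacent
elements from one fused double-length element), classify monomers by
diagnostic sites, and call variants against the consensus.  Writes
results/element_annotations.tsv and results/variants.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from palinsert.annotate import (
    call_variants,
    classify_monomers,
    count_tandem_copies,
    decompose,
    orient_element,
    summarize_variant_sharing,
)
from palinsert.detect import call_panel
from palinsert.panel import build_panel, default_panel_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    panel = build_panel(default_panel_config(args.seed))
    calls = call_panel(panel)
    rows = []
    variants_by_species = {}
    for sp in sorted(calls):
        for call in calls[sp]:
            ori = orient_element(call.inserted_sequence, panel.element)
            if ori.orientation == "unrecognized":
                continue
            comp = decompose(call.inserted_sequence, panel.element, ori.orientation)
            tandem = count_tandem_copies(
                call.inserted_sequence,
                panel.element,
                [panel.pali1, panel.pali2],
                ori.orientation,
            )
            monomers = classify_monomers(comp, panel.element)
            if tandem.copy_number <= 1:
                variants = call_variants(
                    call.inserted_sequence, panel.element, ori.orientation
                )
            else:
                variants = []
                for k, (lo, hi) in enumerate(sorted(tandem.copy_intervals), 1):
                    variants.extend(
                        call_variants(
                            comp.oriented_sequence[lo:hi], panel.element, "forward", k
                        )
                    )
            variants_by_species[sp] = variants
            rows.append(
                {
                    "species": sp,
                    "orientation": ori.orientation,
                    "copy_number": tandem.copy_number,
                    "internal_tsd_evidence": tandem.internal_tsd_evidence is not None,
                    "terminator_repeats": comp.terminator_repeat_count,
                    "monomer_assignment": "/".join(m.assigned for m in monomers),
                    "n_variants": len(variants),
                    "flags": "|".join(tandem.flags) or ".",
                }
            )
    args.out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "element_annotations.tsv", sep="\t", index=False)
    clades = {r.identifier: r.clade for r in panel.records}
    vdf = pd.DataFrame(summarize_variant_sharing(variants_by_species, clades))
    vdf.to_csv(args.out / "variants.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    shared = (vdf["sharing"] == "shared").sum() if len(vdf) else 0
    print(f"\n{len(vdf)} distinct variants across species ({shared} shared).")


if __name__ == "__main__":
    main()
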