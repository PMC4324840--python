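"""End-to-end pipeline: simulate -> detect -> annotate -> palindromes -> tsd
-> phylo -> motifs, driven by one YAML config, writing per-stage TSV/GFF3
outputs and a machine-readable JSON summary.

Reruns with the same config and seed are byte-identical.  Every number in
the summary is recomputable from the stage outputs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .align import Scoring
from .annotate import (
    call_variants,
    count_tandem_copies,
    decompose,
    orient_element,
    summarize_variant_sharing,
)
from .detect import (
    DEFAULT_LOCUS_TOLERANCE,
    DEFAULT_MIN_INSERTION_LENGTH,
    call_panel,
    compare_loci,
)
from .io_formats import (
    AnnotationRecord,
    dump_yaml,
    load_yaml,
    read_jaspar,
    read_newick,
    write_fasta,
    write_gff,
)
from .motifs import element_unique_hits, pwm_from_counts, scan
from .palindrome import find_palindromes, pairing_profile
from .panel import (
    ConfigError,
    PanelConfig,
    SpeciesSpec,
    build_panel,
    default_panel_config,
)
from .phylo import (
    build_matrix,
    consistency_report,
    default_panel_tree,
    fitch_parsimony,
)
from .tsd import classify_truncation, detect_relic, find_tsd


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration.  The seed is always explicit."""

    seed: int
    output_dir: str
    reference: str = "cow"
    mutation_rate: float = 0.0
    min_insertion_length: int = DEFAULT_MIN_INSERTION_LENGTH
    locus_tolerance: int = DEFAULT_LOCUS_TOLERANCE
    motifs_path: str | None = None  # None -> packaged synthetic motif set
    tree_path: str | None = None  # None -> packaged panel tree
    panel: dict | None = None  # PanelConfig overrides (species table etc.)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("seed is mandatory")
        if "output_dir" not in raw:
            raise ConfigError("output_dir is mandatory")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(load_yaml(path))


def panel_config_from_run(config: RunConfig) -> PanelConfig:
    if config.panel is None:
        return default_panel_config(config.seed, config.mutation_rate)
    raw = dict(config.panel)
    species_raw = raw.pop("species", None)
    base = default_panel_config(config.seed, config.mutation_rate)
    if species_raw is not None:
        species = []
        for item in species_raw:
            item = dict(item)
            subs = [tuple(x) for x in item.pop("element_substitutions", [])]
            species.append(SpeciesSpec(element_substitutions=subs, **item))
        base.species = species
    for key, value in raw.items():
        if not hasattr(base, key):
            raise ConfigError(f"unknown panel config key {key!r}")
        setattr(base, key, value)
    return base


def validate_config(raw: dict) -> list[str]:
    """Exhaustive validation of a parsed YAML config.

    Returns findings ("error: ..." / "warning: ...") instead of raising.
    """
    findings: list[str] = []
    try:
        config = RunConfig.from_dict(raw)
    except (ConfigError, TypeError) as exc:
        return [f"error: {exc}"]
    try:
        panel_cfg = panel_config_from_run(config)
    except (ConfigError, TypeError) as exc:
        return [f"error: panel config: {exc}"]
    findings.extend(panel_cfg.validate())
    if config.min_insertion_length != DEFAULT_MIN_INSERTION_LENGTH:
        findings.append(
            f"warning: non-default min_insertion_length {config.min_insertion_length}"
        )
    if config.locus_tolerance != DEFAULT_LOCUS_TOLERANCE:
        findings.append(f"warning: non-default locus_tolerance {config.locus_tolerance}")
    if config.reference not in {s.name for s in panel_cfg.species}:
        findings.append(f"error: reference species {config.reference!r} not in the panel")
    return findings


@dataclasses.dataclass
class RunSummary:
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)


def _write_tsv(rows: list[dict], path: Path) -> None:
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run every stage and write outputs under ``config.output_dir``.

    Any stage failure raises :class:`StageError` naming the stage; the
    summary JSON is written last.
    """
    findings = validate_config(config.to_dict())
    errors = [f for f in findings if f.startswith("error")]
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- simulate -----------------------------------------------------------
    try:
        panel_cfg = panel_config_from_run(config)
        panel = build_panel(panel_cfg)
        write_fasta([r.record for r in panel.records], out / "panel.fasta")
        truth_anns = [a for r in panel.records for a in r.truth]
        write_gff(truth_anns, out / "truth.gff3")
        _write_tsv(panel.truth_table(), out / "truth.tsv")
        resolved = config.to_dict()
        resolved["panel_resolved"] = {
            "n_species": len(panel_cfg.species),
            "total_length": panel_cfg.total_length,
            "tss_offset": panel_cfg.tss_offset,
            "is1": panel_cfg.is1,
            "is2": panel_cfg.is2,
            "mutation_rate": panel_cfg.mutation_rate,
        }
        dump_yaml(resolved, out / "resolved_config.yaml")
        counts["simulate"] = len(panel.records)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # --- detect -------------------------------------------------------------
    try:
        scoring = Scoring()
        calls = call_panel(
            panel, config.reference, scoring, config.min_insertion_length
        )
        nonempty = {sp: cs for sp, cs in calls.items() if cs}
        locus_table = compare_loci(nonempty, config.locus_tolerance) if nonempty else None
        locus_of: dict[tuple[str, int], str] = {}
        if locus_table:
            for locus in locus_table.loci:
                for c in locus.calls:
                    locus_of[(c.query_id, c.ref_position)] = locus.label
        call_rows = []
        for sp in sorted(calls):
            for c in calls[sp]:
                call_rows.append(
                    {
                        "species": sp,
                        "locus": locus_of.get((sp, c.ref_position), "?"),
                        "ref_position": c.ref_position,
                        "tss_distance": c.tss_distance,
                        "length": c.length,
                        "query_start": c.query_start,
                        "query_end": c.query_end,
                    }
                )
        _write_tsv(call_rows, out / "calls.tsv")
        counts["detect"] = len(call_rows)
    except Exception as exc:
        raise StageError("detect", str(exc)) from exc

    # --- annotate -----------------------------------------------------------
    try:
        annotations: list[AnnotationRecord] = []
        variants_by_species: dict[str, list] = {}
        element_intervals: dict[str, list[tuple[int, int]]] = {}
        tandem_by_call: dict[tuple[str, int], object] = {}
        decomposed: dict[tuple[str, int], object] = {}
        for sp in sorted(nonempty):
            rec = panel.by_name(sp)
            for call in nonempty[sp]:
                ori = orient_element(call.inserted_sequence, panel.element, scoring)
                if ori.orientation == "unrecognized":
                    continue
                comp = decompose(call.inserted_sequence, panel.element, ori.orientation, scoring)
                tandem = count_tandem_copies(
                    call.inserted_sequence,
                    panel.element,
                    [panel.pali1, panel.pali2],
                    ori.orientation,
                    scoring,
                )
                comp.copy_number = tandem.copy_number
                comp.internal_tsd_evidence = tandem.internal_tsd_evidence
                decomposed[(sp, call.ref_position)] = comp
                tandem_by_call[(sp, call.ref_position)] = tandem
                n = len(call.inserted_sequence)
                strand = "+" if ori.orientation == "forward" else "-"

                def to_query(lo: int, hi: int) -> tuple[int, int]:
                    # oriented-insert -> query promoter coordinates
                    if ori.orientation == "forward":
                        return call.query_start + lo, call.query_start + hi
                    return call.query_start + n - hi, call.query_start + n - lo

                copies = tandem.copy_intervals or [
                    (comp.intervals["monomer1"][0], comp.intervals["terminator"][1])
                ]
                for k, (lo, hi) in enumerate(sorted(copies), 1):
                    q_lo, q_hi = to_query(lo, hi)
                    annotations.append(
                        AnnotationRecord(
                            sp, q_lo, q_hi, strand, "element",
                            {
                                "locus": locus_of.get((sp, call.ref_position), "?"),
                                "copy_index": k,
                                "copy_number": tandem.copy_number,
                                "terminator_repeats": comp.terminator_repeat_count,
                                "flags": "|".join(tandem.flags) or ".",
                            },
                        )
                    )
                element_intervals.setdefault(sp, []).extend(
                    [to_query(lo, hi) for lo, hi in sorted(copies)]
                )
                if tandem.copy_number <= 1:
                    variants = call_variants(
                        call.inserted_sequence, panel.element, ori.orientation, 1, scoring
                    )
                else:
                    variants = []
                    for k, (lo, hi) in enumerate(sorted(tandem.copy_intervals), 1):
                        seg = comp.oriented_sequence[lo:hi]
                        variants.extend(
                            call_variants(seg, panel.element, "forward", k, scoring)
                        )
                variants_by_species.setdefault(sp, []).extend(variants)
        write_gff(annotations, out / "annotations.gff3")
        clades = {r.identifier: r.clade for r in panel.records}
        variant_rows = summarize_variant_sharing(variants_by_species, clades)
        _write_tsv(variant_rows, out / "variants.tsv")
        counts["annotate"] = len(annotations)
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc

    # --- palindromes --------------------------------------------------------
    try:
        pal_rows = []
        pal_reports: dict[str, dict] = {}
        for rec in panel.records:
            report = {}
            for ann in rec.truth:
                if ann.feature_type != "palindrome":
                    continue
                name = ann.attributes["name"]
                template = panel.pali1 if name == "PALI1" else panel.pali2
                allele = ann.attributes.get("allele", "wild_type")
                allele = None if allele == "wild_type" else allele
                span_seq = rec.sequence[ann.start : ann.end]
                prof = pairing_profile(template, span_seq, allele)
                window_lo = max(0, ann.start - 20)
                window = rec.sequence[window_lo : ann.end + 20]
                found = find_palindromes(window, sequence_id=rec.identifier)
                overlapping = [
                    p
                    for p in found
                    if p.start + window_lo < ann.end and ann.start < p.end + window_lo
                ]
                max_p = max(overlapping, key=lambda p: p.total_length, default=None)
                pal_rows.append(
                    {
                        "species": rec.identifier,
                        "palindrome": name,
                        "allele": allele or "wild_type",
                        "start": ann.start,
                        "end": ann.end,
                        "template_mismatches": prof.n_mismatches,
                        "mismatch_positions": ",".join(map(str, prof.mismatch_positions)) or ".",
                        "max_detected_span": max_p.total_length if max_p else 0,
                        "detected_loop": max_p.loop_length if max_p else ".",
                        "delta_g": round(max_p.delta_g, 3) if max_p else ".",
                    }
                )
                if name == "PALI1":
                    report["pali1_mismatches"] = prof.n_mismatches
                else:
                    report["pali2_max_span"] = max_p.total_length if max_p else 0
            pal_reports[rec.identifier] = report
        _write_tsv(pal_rows, out / "palindromes.tsv")
        counts["palindromes"] = len(pal_rows)
    except Exception as exc:
        raise StageError("palindromes", str(exc)) from exc

    # --- tsd ----------------------------------------------------------------
    try:
        tsd_rows = []
        relic_rows = []
        for sp in sorted(nonempty):
            rec = panel.by_name(sp)
            for call in nonempty[sp]:
                comp = decomposed.get((sp, call.ref_position))
                if comp is None:
                    continue
                intervals = sorted(element_intervals.get(sp, []))
                if not intervals:
                    continue
                elem_lo = min(lo for lo, _ in intervals)
                elem_hi = max(hi for _, hi in intervals)
                flank5 = rec.sequence[max(0, call.query_start - 30) : call.query_start]
                flank3 = rec.sequence[elem_hi : elem_hi + 30]
                tsd = find_tsd(flank5, flank3)
                if tsd is not None:
                    at_is1 = abs(call.ref_position - panel.config.is1) <= config.locus_tolerance
                    trunc = classify_truncation(
                        tsd.duplicated_sequence,
                        panel.pali1 if at_is1 else panel.pali2,
                        allele=None if at_is1 else "eland",
                        copy_id=f"{sp}:3prime",
                    )
                    tsd_rows.append(
                        {
                            "species": sp,
                            "locus": locus_of.get((sp, call.ref_position), "?"),
                            "duplicated_sequence": tsd.duplicated_sequence,
                            "match_length": tsd.match_length,
                            "mismatches": tsd.mismatches,
                            "truncated_5prime": trunc.truncated_5prime,
                            "truncated_3prime": trunc.truncated_3prime,
                            "retained_fraction": round(trunc.retained_fraction, 3),
                        }
                    )
                relic = detect_relic(comp, [panel.pali1, panel.pali2])
                if relic is not None:
                    relic_rows.append(
                        {
                            "species": sp,
                            "locus": locus_of.get((sp, call.ref_position), "?"),
                            "polya_length": relic.polya_interval[1] - relic.polya_interval[0],
                            "partial_template": relic.template_name,
                            "partial_length": relic.matched_length,
                            "terminator_repeats_before": relic.terminator_repeats_before,
                            "terminator_repeats_after": relic.terminator_repeats_after,
                        }
                    )
        _write_tsv(tsd_rows, out / "tsd.tsv")
        _write_tsv(relic_rows, out / "relics.tsv")
        counts["tsd"] = len(tsd_rows)
        counts["relics"] = len(relic_rows)
    except Exception as exc:
        raise StageError("tsd", str(exc)) from exc

    # --- phylo --------------------------------------------------------------
    try:
        species_list = [r.identifier for r in panel.records]
        presence = {sp: set() for sp in species_list}
        for row in call_rows:
            presence[row["species"]].add(row["locus"])
        matrix = build_matrix(presence, pal_reports, species_list)
        tree = (
            read_newick(config.tree_path) if config.tree_path else default_panel_tree()
        )
        parsimony = fitch_parsimony(tree, matrix)
        flags = consistency_report(matrix)
        _write_tsv(matrix.to_rows(), out / "matrix.tsv")
        _write_tsv(
            [
                {
                    "character": c,
                    "min_changes": r.min_changes,
                    "homoplasy": r.homoplasy,
                }
                for c, r in sorted(parsimony.per_character.items())
            ],
            out / "parsimony.tsv",
        )
        _write_tsv(
            [
                {"species": f.species, "kind": f.kind, "detail": f.detail}
                for f in flags
            ],
            out / "flags.tsv",
        )
        counts["phylo_characters"] = len(matrix.characters)
    except Exception as exc:
        raise StageError("phylo", str(exc)) from exc

    # --- motifs -------------------------------------------------------------
    try:
        if config.motifs_path:
            count_mats = read_jaspar(config.motifs_path)
        else:
            path = resources.files("palinsert.data").joinpath("synthetic_motifs.jaspar")
            count_mats = read_jaspar(path)
        pwms = [pwm_from_counts(m) for m in count_mats]
        hit_rows = []
        class_rows = []
        # the CpG-island start is upstream of the insertion loci, so it is a
        # stable coordinate across species; the region end tracks each TSS
        cpg_lo = panel.config.cpg_island[0]
        for rec in panel.records:
            region = (cpg_lo, min(rec.tss_position + 50, len(rec.sequence)))
            intervals = element_intervals.get(rec.identifier, [])
            hits = [h for p in pwms for h in scan(rec.sequence, p, rec.identifier)]
            classes = element_unique_hits(
                hits, intervals, region, motif_ids=[p.motif_id for p in pwms]
            )
            for h in hits:
                if region[0] <= h.start and h.end <= region[1]:
                    hit_rows.append(
                        {
                            "species": h.sequence_id,
                            "motif": h.motif_id,
                            "start": h.start,
                            "end": h.end,
                            "strand": h.strand,
                            "score": round(h.score, 3),
                            "inside_element": h.inside_element,
                        }
                    )
            for motif_id, cls in sorted(classes.items()):
                class_rows.append(
                    {
                        "species": rec.identifier,
                        "motif": motif_id,
                        "category": cls.category,
                        "inside_count": cls.inside_count,
                        "outside_count": cls.outside_count,
                        "enrichment": cls.enrichment,
                    }
                )
        _write_tsv(hit_rows, out / "motif_hits.tsv")
        _write_tsv(class_rows, out / "motif_classes.tsv")
        counts["motif_hits"] = len(hit_rows)
    except Exception as exc:
        raise StageError("motifs", str(exc)) from exc

    # --- summary ------------------------------------------------------------
    summary = RunSummary(
        {
            "tool_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stage_counts": counts,
            "n_species": len(panel.records),
            "n_element_bearing": len(nonempty),
            "loci": [
                {
                    "label": locus.label,
                    "position": locus.position,
                    "species": locus.species,
                }
                for locus in (locus_table.loci if locus_table else [])
            ],
            "locus_distances": {
                f"{a}-{b}": d for (a, b), d in (locus_table.distances() if locus_table else {}).items()
            },
            "character_matrix": {
                c: {sp: str(v) for sp, v in states.items()}
                for c, states in matrix.characters.items()
            },
            "parsimony": {
                c: {"min_changes": r.min_changes, "homoplasy": r.homoplasy}
                for c, r in parsimony.per_character.items()
            },
            "consistency_flags": [
                {"species": f.species, "kind": f.kind} for f in flags
            ],
        }
    )
    (out / "summary.json").write_text(summary.to_json() + "\n")
    return summary


def summary_hash(summary: RunSummary) -> str:
    return hashlib.sha256(summary.to_json().encode()).hexdigest()
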