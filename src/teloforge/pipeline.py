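"""End-to-end orchestration: simulate -> digest -> align -> call -> trio ->
validate -> duplication families -> report.

Each stage reads its inputs from and writes its outputs to a run directory,
so stages can be run separately or as one pass; a rerun with the same
configuration and seed reproduces the bundle byte for byte.  When the run
directory carries a simulation truth ledger, calls are scored against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dupfamily as df
from . import nanopore as npv
from .alignment import AlignmentParams, LabelAlignment, align, read_xmap, write_xmap
from .label_io import LabelMap, LabelStats, digest, interlabel_stats, merge_labels, read_cmap, write_cmap
from .simulate import (
    SimConfig, SimTruth, default_config, read_fasta, segdup_table_from_truth,
    simulate_contig_maps, simulate_reference, simulate_terminal_read, simulate_trio,
    write_fasta,
)
from .terminus import (
    TerminusCall, alignment_is_confident, anchor_terminus, call_terminus,
    classify_extension, compute_threshold, detect_diploid, trio_inheritance,
)

__all__ = ["PipelineConfig", "run_end_to_end", "paralogy_report", "ALL_STAGES"]

log = logging.getLogger("teloforge")

ALL_STAGES = ("simulate", "digest", "align", "call", "trio", "validate", "dupfam", "report")

_SAMPLES = {"father": ("f1", "f2"), "mother": ("m1", "m2"), "child": ("c1", "c2")}


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serialisable."""

    sim: SimConfig = field(default_factory=default_config)
    stages: tuple[str, ...] = ALL_STAGES
    merge_distance: float = 450.0
    threshold_k: float = 3.0
    max_skip: int = 6
    min_labels: int = 3
    match_bonus: float = 3.0
    max_matches: int = 5
    terminal_window: float = 1_000_000.0
    category_min_coverage: float = 0.5
    trio_tolerance: int = 1
    window_labels: int = 10
    subtel_window: int = 1_000_000
    min_cn: int = 22
    validation_read_error: float = 0.05
    validation_terminal_len: int = 100_000
    candidate_refs: int = 2
    anchor_min_labels: int = 10

    def align_params(self, **over) -> AlignmentParams:
        kw = dict(
            max_skip=self.max_skip, min_labels=self.min_labels,
            match_bonus=self.match_bonus, max_matches=self.max_matches,
        )
        kw.update(over)
        return AlignmentParams(**kw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["sim"] = SimConfig.from_dict(d.get("sim", {}))
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)


# ---------------------------------------------------------------------------
# helpers


def _setup_log(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)


def _interval_signature(labels: np.ndarray, binsize: float = 500.0) -> set:
    if labels.size < 3:
        return set()
    iv = np.diff(labels)
    a = np.round(iv[:-1] / binsize)
    b = np.round(iv[1:] / binsize)
    return set(zip(a.tolist(), b.tolist())) | set(zip(b.tolist(), a.tolist()))


def _pooled_stats(maps: Sequence[LabelMap]) -> LabelStats:
    diffs = np.concatenate([np.diff(m.labels) for m in maps if m.n_labels >= 2])
    d = diffs / 1000.0
    return LabelStats(float(d.mean()), float(d.std()), int(d.size), 0)


def _hap_of(contig_id: str) -> str:
    return contig_id.split("_", 1)[0]


def _sample_of(contig_id: str) -> str:
    return {"f": "father", "m": "mother", "c": "child"}[contig_id[0]]


def _load_ref_maps(outdir: Path, cfg: PipelineConfig) -> dict[str, LabelMap]:
    maps = read_cmap(outdir / "ref.cmap")
    return {
        m.id: LabelMap(m.id, m.length, merge_labels(m.labels, cfg.merge_distance))
        for m in maps
    }


def _load_contig_maps(outdir: Path, cfg: PipelineConfig) -> dict[str, LabelMap]:
    maps = read_cmap(outdir / "contigs.cmap")
    return {
        m.id: LabelMap(m.id, m.length, merge_labels(m.labels, cfg.merge_distance))
        for m in maps
    }


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    sim = cfg.sim
    log.info(f"simulate: seed={seed} n_chrom={sim.n_chromosomes} len={sim.chrom_length}")
    sim.seed = seed
    reference, truth = simulate_reference(sim)
    father, mother, child, truth = simulate_trio(reference, sim.event_list, seed, truth)
    write_fasta(reference, outdir / "ref.fasta")
    haps = {**father, **mother, **child}
    for hap, genome in haps.items():
        write_fasta(genome, outdir / f"hap_{hap}.fasta")
    truth.to_json(outdir / "truth.json")
    table = segdup_table_from_truth(truth, genome=reference, both_orders=True)
    table.to_csv(outdir / "segdups.tsv", sep="\t", index=False)
    # noisy optical contigs: one per haplotype chromosome
    contigs: list[LabelMap] = []
    for hap, genome in haps.items():
        named = {f"{hap}_{c}": s for c, s in genome.items()}
        contigs.extend(
            simulate_contig_maps(named, sim.enzyme_motif, sim.contig_noise, seed)
        )
    write_cmap(contigs, outdir / "contigs.cmap")


def stage_digest(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    reference = read_fasta(outdir / "ref.fasta")
    maps = [
        LabelMap(name, float(len(seq)), digest(seq, cfg.sim.enzyme_motif))
        for name, seq in reference.items()
    ]
    write_cmap(maps, outdir / "ref.cmap")
    merged = [
        LabelMap(m.id, m.length, merge_labels(m.labels, cfg.merge_distance)) for m in maps
    ]
    stats = _pooled_stats(merged)
    model = compute_threshold(stats, cfg.threshold_k)
    log.info(
        f"digest: {sum(m.n_labels for m in maps)} labels, merged "
        f"{sum(m.n_labels for m in merged)}; spacing {stats.mean_interval:.2f}"
        f"+/-{stats.sd_interval:.2f} kb; threshold {model.reported} kb"
    )
    (outdir / "threshold.json").write_text(json.dumps(asdict(model), indent=1))


def stage_align(cfg: PipelineConfig, outdir: Path, seed: int) -> None:
    refs = _load_ref_maps(outdir, cfg)
    contigs = _load_contig_maps(outdir, cfg)
    params = cfg.align_params(mode="endoutlier")
    ref_sigs = {rid: _interval_signature(r.labels) for rid, r in refs.items()}
    results: list[LabelAlignment] = []
    for cid, cm in contigs.items():
        if cm.n_labels < params.min_labels:
            log.info(f"align: {cid} skipped ({cm.n_labels} labels)")
            continue
        qsig = _interval_signature(cm.labels)
        scored = sorted(
            ((len(qsig & ref_sigs[rid]), rid) for rid in refs), reverse=True
        )
        candidates = [rid for hits, rid in scored[: cfg.candidate_refs] if hits > 0]
        if not candidates:
            candidates = list(refs)
        results.extend(align(cm, [refs[r] for r in candidates], params))
    write_xmap(results, outdir / "alignments.xmap")
    log.info(f"align: {len(results)} alignments, params max_skip={params.max_skip}")


def _anchor_all(
    cfg: PipelineConfig,
    refs: Mapping[str, LabelMap],
    contigs: Mapping[str, LabelMap],
    alignments: Sequence[LabelAlignment],
    threshold_bp: float,
    samples: Sequence[str],
) -> list[TerminusCall]:
    calls: list[TerminusCall] = []
    ref_list = list(refs.values())
    params = cfg.align_params(mode="endoutlier")
    for sample in samples:
        sample_alns = [a for a in alignments if _sample_of(a.query_id) == sample]
        for chrom, ref in refs.items():
            for arm in ("p", "q"):
                anchored = anchor_terminus(
                    sample_alns, chrom, arm, ref, contigs, cfg.terminal_window,
                    min_pairs=cfg.anchor_min_labels,
                    min_score_per_interval=cfg.match_bonus / 2.0,
                )
                if anchored is None:
                    calls.append(TerminusCall(sample, chrom, arm, status="excluded"))
                    continue
                call = call_terminus(
                    anchored, contigs[anchored.query_id], ref, arm,
                    threshold_bp, sample=sample,
                )
                call = classify_extension(
                    call, contigs[anchored.query_id], ref_list, params,
                    cfg.category_min_coverage, cfg.terminal_window,
                )
                calls.append(call)
    return calls


def _calls_to_frame(calls: Sequence[TerminusCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample, "chrom": c.chrom, "arm": c.arm,
                "status": c.status,
                "extension_len": round(c.extension_len, 1),
                "missing_len": round(c.missing_len, 1),
                "category": c.category if c.category else 0,
                "origins": ";".join(
                    f"{o.chrom}{o.arm}:{o.span[0]:.0f}-{o.span[1]:.0f}{o.orientation}"
                    for o in c.origins
                ),
                "anchor_contig": c.anchor_contig or "",
                "anchor_score": round(c.anchor_score, 2),
                "flags": ";".join(c.flags),
            }
        )
    return pd.DataFrame(rows)


def stage_call(cfg: PipelineConfig, outdir: Path, seed: int) -> list[TerminusCall]:
    refs = _load_ref_maps(outdir, cfg)
    contigs = _load_contig_maps(outdir, cfg)
    alignments = read_xmap(outdir / "alignments.xmap")
    model = json.loads((outdir / "threshold.json").read_text())
    threshold_bp = model["threshold"] * 1000.0
    samples = sorted({_sample_of(c) for c in contigs})
    calls = _anchor_all(cfg, refs, contigs, alignments, threshold_bp, samples)
    frame = _calls_to_frame(calls)

    # diploid termini: allele classes among a sample's contigs at one terminus
    allele_rows = []
    for sample in samples:
        sample_alns = [a for a in alignments if _sample_of(a.query_id) == sample]
        for chrom, ref in refs.items():
            for arm in ("p", "q"):
                cands = {}
                for a in sample_alns:
                    if a.ref_id != chrom:
                        continue
                    from .terminus import _contig_distal_is_high, _ref_distality
                    d = min(
                        _ref_distality(ref.labels[j], arm, ref.length)
                        for j in a.ref_indices()
                    )
                    if (
                        d <= cfg.terminal_window
                        and alignment_is_confident(
                            a, cfg.anchor_min_labels, cfg.match_bonus / 2.0
                        )
                        and a.query_id not in cands
                    ):
                        cands[a.query_id] = (
                            a.query_id, contigs[a.query_id],
                            _contig_distal_is_high(arm, a.orientation),
                        )
                if cands:
                    alleles = detect_diploid(
                        list(cands.values()), cfg.trio_tolerance, cfg.window_labels
                    )
                    allele_rows.append(
                        {
                            "sample": sample, "chrom": chrom, "arm": arm,
                            "n_alleles": len(alleles),
                            "alleles": "|".join(",".join(a) for a in alleles),
                        }
                    )
    frame.to_csv(outdir / "termini.tsv", sep="\t", index=False)
    pd.DataFrame(allele_rows).to_csv(outdir / "alleles.tsv", sep="\t", index=False)
    _write_calls_json(calls, outdir / "termini.json")
    log.info(f"call: {len(calls)} terminus calls, threshold {threshold_bp/1000:.1f} kb")
    _score_against_truth(cfg, outdir, calls)
    return calls


def _write_calls_json(calls: Sequence[TerminusCall], path: Path) -> None:
    out = []
    for c in calls:
        d = asdict(c)
        d["origins"] = [asdict(o) for o in c.origins]
        out.append(d)
    path.write_text(json.dumps(out, indent=1))


def _read_calls_json(path: Path) -> list[TerminusCall]:
    from .terminus import Origin

    calls = []
    for d in json.loads(path.read_text()):
        origins = [Origin(**{**o, "span": tuple(o["span"])}) for o in d.pop("origins")]
        c = TerminusCall(**d)
        c.origins = origins
        calls.append(c)
    return calls


def _score_against_truth(
    cfg: PipelineConfig, outdir: Path, calls: Sequence[TerminusCall]
) -> None:
    truth_path = outdir / "truth.json"
    if not truth_path.exists():
        return
    truth = SimTruth.from_json(truth_path)
    model = json.loads((outdir / "threshold.json").read_text())
    threshold_bp = model["threshold"] * 1000.0
    rows = []
    for c in calls:
        if c.status == "excluded" or not c.anchor_contig:
            continue
        hap = _hap_of(c.anchor_contig)
        expected = truth.expected_status(hap, c.chrom, c.arm, threshold_bp)
        events = truth.events_for(hap, c.chrom, c.arm)
        donor = next((e.donor for e in events if e.donor), None)
        origin_ok = ""
        if donor and c.origins:
            origin_ok = str(
                (c.origins[0].chrom, c.origins[0].arm) == tuple(donor)
            )
        rows.append(
            {
                "sample": c.sample, "chrom": c.chrom, "arm": c.arm,
                "anchored_hap": hap, "called": c.status, "expected": expected,
                "status_correct": c.status == expected,
                "origin_correct": origin_ok,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "score.tsv", sep="\t", index=False)
    if len(frame):
        log.info(
            f"score: {frame.status_correct.mean():.3f} status recovery "
            f"({int(frame.status_correct.sum())}/{len(frame)})"
        )


def stage_trio(cfg: PipelineConfig, outdir: Path, seed: int) -> pd.DataFrame:
    from .terminus import _contig_distal_is_high

    refs = _load_ref_maps(outdir, cfg)
    contigs = _load_contig_maps(outdir, cfg)
    alignments = read_xmap(outdir / "alignments.xmap")
    truth = (
        SimTruth.from_json(outdir / "truth.json")
        if (outdir / "truth.json").exists()
        else None
    )
    rows = []
    for chrom, ref in refs.items():
        for arm in ("p", "q"):
            anchored = {}
            for sample in _SAMPLES:
                sample_alns = [
                    a for a in alignments if _sample_of(a.query_id) == sample
                ]
                a = anchor_terminus(
                    sample_alns, chrom, arm, ref, contigs, cfg.terminal_window,
                    min_pairs=cfg.anchor_min_labels,
                    min_score_per_interval=cfg.match_bonus / 2.0,
                )
                if a is not None:
                    anchored[sample] = (
                        contigs[a.query_id],
                        _contig_distal_is_high(arm, a.orientation),
                        a.query_id,
                    )
            if "child" not in anchored:
                continue
            tc = trio_inheritance(
                anchored["child"][:2],
                anchored.get("father", (None,))[:2] if "father" in anchored else None,
                anchored.get("mother", (None,))[:2] if "mother" in anchored else None,
                chrom, arm, cfg.trio_tolerance, cfg.window_labels,
            )
            row = {
                "chrom": chrom, "arm": arm,
                "parent_of_origin": tc.parent_of_origin,
                "diff_father": tc.diff_father, "diff_mother": tc.diff_mother,
                "child_contig": anchored["child"][2],
            }
            if truth is not None:
                # a parent is a valid origin when either of its haplotypes
                # carries the child's anchored allele (the chromosome end is
                # a dominant marker: each side is represented by its longest
                # allele, so the transmitting haplotype itself may be hidden)
                hap = _hap_of(anchored["child"][2])
                child_sig = _event_signature(truth, hap, chrom, arm)
                valid = {
                    parent
                    for parent, haps in (("father", ("f1", "f2")), ("mother", ("m1", "m2")))
                    if any(
                        _event_signature(truth, h, chrom, arm) == child_sig
                        for h in haps
                    )
                }
                called = tc.parent_of_origin
                row["valid_parents"] = ",".join(sorted(valid))
                row["inheritance_correct"] = (
                    valid == {"father", "mother"} if called == "both"
                    else not valid if called == "neither"
                    else called in valid
                )
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "trio.tsv", sep="\t", index=False)
    if truth is not None and len(frame):
        log.info(
            f"trio: {frame.inheritance_correct.mean():.3f} inheritance recovery"
        )
    return frame


def _event_signature(truth: SimTruth, hap: str, chrom: str, arm: str) -> tuple:
    evs = truth.events_for(hap, chrom, arm)
    return tuple(
        sorted((e.kind, e.length, e.copies or 0, e.donor or ()) for e in evs)
    )


def stage_validate(cfg: PipelineConfig, outdir: Path, seed: int) -> pd.DataFrame:
    """Long-read validation of the child's category-1 extension calls, plus
    tandem-repeat estimation on extension termini whose origin is their own
    terminus."""
    calls = _read_calls_json(outdir / "termini.json")
    reference = read_fasta(outdir / "ref.fasta")
    rows = []
    for c in calls:
        if "extension" not in c.status or c.category != 1:
            continue
        hap = _hap_of(c.anchor_contig)
        hap_genome = read_fasta(outdir / f"hap_{hap}.fasta")
        read_len = int(c.extension_len) + cfg.validation_terminal_len
        read = simulate_terminal_read(
            hap_genome, c.chrom, c.arm, read_len, cfg.validation_read_error, seed
        )
        pred = npv.build_prediction(
            reference, c, terminal_len=cfg.validation_terminal_len
        )
        verdict = npv.validate_extension(read.sequence, pred)
        tandem = npv.estimate_tandem(
            read.sequence, window=min(read_len, int(c.extension_len) + 20_000)
        )
        rows.append(
            {
                "sample": c.sample, "chrom": c.chrom, "arm": c.arm,
                "origin": f"{c.origins[0].chrom}{c.origins[0].arm}",
                "confirmed": verdict.confirmed,
                "covered_fraction": round(verdict.covered_fraction, 3),
                "internal_deletion": verdict.internal_deletion,
                "tandem_unit": round(tandem.unit_len, 0),
                "tandem_copies": tandem.copies if tandem.support else 1,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    if len(frame):
        log.info(f"validate: {int(frame.confirmed.sum())}/{len(frame)} confirmed")
    return frame


def stage_dupfam(cfg: PipelineConfig, outdir: Path, seed: int) -> pd.DataFrame:
    pairs = df.read_segdup_table(outdir / "segdups.tsv")
    truth = SimTruth.from_json(outdir / "truth.json")
    chrom_lengths = truth.chrom_lengths
    families = df.detect_families(pairs, chrom_lengths, cfg.min_cn)
    families = df.subtelomeric_filter(families, chrom_lengths, cfg.subtel_window)
    genome_bp = sum(chrom_lengths.values())
    subtel_bp = sum(min(2 * cfg.subtel_window, L) for L in chrom_lengths.values())
    fam_rows, age_rows = [], []
    for k, fam in enumerate(families):
        fold, p = df.enrichment_test(fam, subtel_bp, genome_bp)
        divs = []
        for pr in pairs:
            a = (pr.chrom_a, pr.start_a, pr.end_a)
            b = (pr.chrom_b, pr.start_b, pr.end_b)
            if a in fam.members and b in fam.members and a < b:
                divs.append(100.0 * (1.0 - pr.identity))
        ages = [df.date_duplication(d).age for d in divs] or [0.0]
        fam_rows.append(
            {
                "family": k,
                "core": f"{fam.core[0]}:{fam.core[1]}-{fam.core[2]}",
                "core_length": fam.core_length,
                "n_members": fam.n_members,
                "n_subtelomeric": fam.n_subtelomeric,
                "fold_enrichment": round(fold, 2),
                "p_value": f"{p:.3e}",
            }
        )
        age_rows.append(
            {
                "family": k,
                "min_divergence_pct": round(min(divs), 4) if divs else 0.0,
                "max_divergence_pct": round(max(divs), 4) if divs else 0.0,
                "min_age_myr": round(min(ages), 3),
                "max_age_myr": round(max(ages), 3),
            }
        )
    pd.DataFrame(fam_rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
    pd.DataFrame(age_rows).to_csv(outdir / "ages.tsv", sep="\t", index=False)
    log.info(f"dupfam: {len(families)} subtelomeric families (min_cn={cfg.min_cn})")
    return pd.DataFrame(fam_rows)


def paralogy_report(
    calls: Sequence[TerminusCall],
    trio: pd.DataFrame | None = None,
    alleles: pd.DataFrame | None = None,
) -> str:
    """Text paralogy summary: per terminus, the anchored contig, its status,
    origins with orientation, and allele/inheritance context."""
    lines = ["# paralogy report", ""]
    by_terminus: dict[tuple[str, str], list[TerminusCall]] = {}
    for c in calls:
        by_terminus.setdefault((c.chrom, c.arm), []).append(c)
    for (chrom, arm), group in sorted(by_terminus.items()):
        lines.append(f"== {chrom}{arm} ==")
        for c in group:
            desc = f"  {c.sample:<8} {c.status:<22}"
            if c.anchor_contig:
                desc += f" contig={c.anchor_contig} score={c.anchor_score:.1f}"
            if "extension" in c.status:
                desc += f" ext={c.extension_len:.0f}bp cat={c.category}"
            if "missing" in c.status:
                desc += f" miss={c.missing_len:.0f}bp"
            lines.append(desc)
            for o in c.origins:
                lines.append(
                    f"           origin {o.chrom}{o.arm} "
                    f"{o.span[0]:.0f}-{o.span[1]:.0f} ({o.orientation}) "
                    f"coverage={o.coverage:.2f}"
                )
        if alleles is not None and len(alleles):
            sub = alleles[(alleles.chrom == chrom) & (alleles.arm == arm)]
            for r in sub.itertuples():
                if r.n_alleles > 1:
                    lines.append(f"  {r.sample}: {r.n_alleles} alleles ({r.alleles})")
        if trio is not None and len(trio):
            sub = trio[(trio.chrom == chrom) & (trio.arm == arm)]
            for r in sub.itertuples():
                lines.append(f"  inheritance: {r.parent_of_origin}")
        lines.append("")
    return "\n".join(lines)


def stage_report(cfg: PipelineConfig, outdir: Path, seed: int) -> str:
    calls = _read_calls_json(outdir / "termini.json")
    trio = (
        pd.read_csv(outdir / "trio.tsv", sep="\t")
        if (outdir / "trio.tsv").exists()
        else None
    )
    alleles = (
        pd.read_csv(outdir / "alleles.tsv", sep="\t")
        if (outdir / "alleles.tsv").exists()
        else None
    )
    text = paralogy_report(calls, trio, alleles)
    (outdir / "report.txt").write_text(text)
    return text


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "digest": stage_digest,
    "align": stage_align,
    "call": stage_call,
    "trio": stage_trio,
    "validate": stage_validate,
    "dupfam": stage_dupfam,
    "report": stage_report,
}


def run_end_to_end(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    stages: Sequence[str] | None = None,
) -> dict:
    """Run the configured stages in order; returns {stage: result}.

    A stage failure is logged with its stage name and aborts the remaining
    stages (raised to the caller; the CLI converts it to a nonzero exit).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir)
    seed = config.sim.seed if seed is None else seed
    stages = tuple(stages if stages is not None else config.stages)
    config.to_yaml(outdir / "config_used.yaml")
    results: dict = {}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        log.info(f"stage {stage}: start")
        try:
            results[stage] = _STAGE_FUNCS[stage](config, outdir, seed)
        except Exception:
            log.exception(f"stage {stage}: FAILED; downstream stages skipped")
            raise
    return results
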