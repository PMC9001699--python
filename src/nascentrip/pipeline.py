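"""End-to-end orchestration: simulate -> callpeaks -> annotate -> localize
-> motifprep, with a machine-readable run manifest.

All stage randomness derives from one top-level seed via stable
stage-name hashing, so individual stages re-run in isolation reproduce
the full run's behaviour.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import pandas as pd

from . import __version__
from .genomic_io import (
    read_bed,
    read_fasta,
    read_fraction_table,
    read_gtf,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .motifprep import (
    MotifPrepConfig,
    extract_background,
    extract_foreground,
    ga_enrichment_report,
)
from .peakcall import PeakCallConfig, call_peaks
from .simulate import SimulationConfig, simulate_dataset
from .transcript_context import (
    annotation_summary,
    annotation_table,
    classify_localization,
    classify_peak,
    localization_summary,
    localization_table,
    quant_from_counts,
)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed (< 2**31) from the top-level seed."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0x7FFFFFFF)) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_callpeaks(rip_paths, ctrl_paths, gtf_path, out_dir,
                  config: PeakCallConfig | None = None,
                  write_tracks: bool = True) -> dict:
    """Peak-call stage on BED/GTF files; writes BEDs, bedGraphs, run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or PeakCallConfig()
    rip_sets = [read_bed(p) for p in rip_paths]
    ctrl_sets = [read_bed(p) for p in ctrl_paths]
    genes = read_gtf(gtf_path)

    track_files: list[str] = []

    def emit(label, strand, fold, rip_sm, ctrl_sm):
        if not write_tracks:
            return
        tag = {"+": "plus", "-": "minus", ".": "both"}[strand]
        for kind, track in (("fold", fold), ("rip_cov", rip_sm), ("ctrl_cov", ctrl_sm)):
            path = out / f"{label}.{kind}.{tag}.bedGraph"
            write_bedgraph(track, path)
            track_files.append(path.name)

    per_rep, reproducible, run_log = call_peaks(
        rip_sets, ctrl_sets, genes, config, emit_tracks=emit
    )
    for i, peaks in enumerate(per_rep, start=1):
        write_bed(peaks, out / f"peaks_rep{i}.bed")
    write_bed(reproducible, out / "reproducible_peaks.bed")
    run_log["outputs"] = {
        "per_replicate": [f"peaks_rep{i}.bed" for i in (1, 2)],
        "reproducible": "reproducible_peaks.bed",
        "tracks": track_files,
    }
    with open(out / "callpeaks_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
    return {"per_rep": per_rep, "reproducible": reproducible, "log": run_log}


def run_annotate(peaks, gtf_path, out_dir) -> dict:
    """Annotate peaks (objects or a BED path) against a GTF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = read_gtf(gtf_path)
    if isinstance(peaks, (str, Path)):
        peaks = read_bed(peaks)
    calls = [
        classify_peak(p.interval if hasattr(p, "interval") else p, genes)
        for p in peaks
    ]
    table = annotation_table(peaks, calls)
    table.to_csv(out / "annotation.tsv", sep="\t", index=False)
    summary = annotation_summary(calls) if calls else {}
    rows = []
    for name, series in summary.items():
        for label, prop in series.items():
            rows.append({"table": name, "label": label, "proportion": prop})
    pd.DataFrame(rows).to_csv(out / "annotation_summary.tsv", sep="\t", index=False)
    return {"calls": calls, "summary": summary}


def run_localize(counts_path, totals_path, out_dir) -> dict:
    """Localization stage from a pre-computed fraction count table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_fraction_table(counts_path)
    totals_df = pd.read_csv(totals_path, sep="\t")
    totals = dict(zip(totals_df["fraction"], totals_df["total"].astype(int)))
    quants = [quant_from_counts(row, totals) for _, row in df.iterrows()]
    calls = [classify_localization(q) for q in quants]
    localization_table(quants, calls).to_csv(
        out / "localization.tsv", sep="\t", index=False
    )
    summary = localization_summary(calls)
    pd.DataFrame([summary]).to_csv(
        out / "localization_summary.tsv", sep="\t", index=False
    )
    return {"quants": quants, "calls": calls, "summary": summary}


def run_motifprep(peaks, fasta_path, out_dir,
                  config: MotifPrepConfig | None = None, seed: int = 0) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or MotifPrepConfig()
    if isinstance(peaks, (str, Path)):
        peaks = read_bed(peaks)
    sequences = read_fasta(fasta_path)
    fg = extract_foreground(peaks, sequences, config)
    bg = extract_background(peaks, sequences, config)
    write_fasta(fg, out / "foreground.fa")
    write_fasta(bg, out / "background.fa")
    report = ga_enrichment_report(fg, bg, seed=seed) if fg and bg else {}
    if report:
        pd.DataFrame([report]).to_csv(out / "ga_report.tsv", sep="\t", index=False)
    return {"foreground": fg, "background": bg, "ga_report": report}


def run_all(out_dir, seed: int = 7,
            sim_config: SimulationConfig | None = None,
            peak_config: PeakCallConfig | None = None,
            motif_config: MotifPrepConfig | None = None,
            inputs: dict | None = None,
            write_tracks: bool = True) -> dict:
    """Full pipeline run; simulates inputs unless ``inputs`` names real
    files (keys: rip (2 paths), ctrl (2 paths), gtf, ref, fractions,
    totals).  Returns the manifest (also written as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    if inputs is None:
        sim_config = sim_config or SimulationConfig(seed=stage_seed(seed, "simulate"))
        paths = simulate_dataset(sim_config, out / "simulation")
        inputs = {
            "rip": [paths["beds"]["rip1"], paths["beds"]["rip2"]],
            "ctrl": [paths["beds"]["igg1"], paths["beds"]["igg2"]],
            "gtf": paths["gtf"],
            "ref": paths["ref"],
            "fractions": paths["fractions"],
            "totals": paths["totals"],
        }
        def _rel(p):
            return str(Path(p).relative_to(out))

        manifest["stages"]["simulate"] = {
            "seed": sim_config.seed,
            "outputs": {
                k: ({s: _rel(p) for s, p in v.items()} if isinstance(v, dict)
                    else _rel(v))
                for k, v in paths.items()
            },
        }
    for key in ("rip", "ctrl", "gtf"):
        if key not in inputs:
            raise ValueError(f"missing required input: {key}")
    manifest["input_checksums"] = {
        name: (
            [_sha256(Path(p)) for p in val] if isinstance(val, list)
            else _sha256(Path(val))
        )
        for name, val in inputs.items()
    }

    peak_config = peak_config or PeakCallConfig(seed=stage_seed(seed, "callpeaks"))
    pk = run_callpeaks(
        inputs["rip"], inputs["ctrl"], inputs["gtf"], out / "peaks",
        peak_config, write_tracks=write_tracks,
    )
    manifest["stages"]["callpeaks"] = pk["log"]

    ann = run_annotate(pk["reproducible"], inputs["gtf"], out / "annotation")
    manifest["stages"]["annotate"] = {
        "n_peaks_annotated": len(ann["calls"]),
        "category_proportions": (
            ann["summary"]["category"].to_dict() if ann["calls"] else {}
        ),
    }

    if "fractions" in inputs and "totals" in inputs:
        loc = run_localize(inputs["fractions"], inputs["totals"], out / "localization")
        manifest["stages"]["localize"] = {
            "n_fragments": loc["summary"]["n"],
            "fraction_nuclear": loc["summary"]["fraction_nuclear"],
            "fraction_polya_minus_among_nuclear": (
                loc["summary"]["fraction_polya_minus_among_nuclear"]
            ),
        }

    if "ref" in inputs:
        mp = run_motifprep(
            pk["reproducible"], inputs["ref"], out / "motif",
            motif_config, seed=stage_seed(seed, "motifprep"),
        )
        manifest["stages"]["motifprep"] = {
            "n_foreground": len(mp["foreground"]),
            "n_background": len(mp["background"]),
            "ga_report": mp["ga_report"],
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
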