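"""End-to-end orchestration: census, selection, PHI test, cassette scan and
topology shift, written as a reproducible report bundle.

One master seed deterministically derives every stage seed (CRC32 of
``"<master>:<stage>"``, kept below 2**31), so re-running a config reproduces
every output byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import cassette_scan, recombination, selection
from .core_io import (
    Alignment,
    ColumnInterval,
    UnknownIdError,
    read_alignment,
    variable_columns,
    write_intervals,
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one master seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class RunConfig:
    alignment_path: str
    recipient: str
    background: tuple[str, ...]
    candidates: tuple[str, ...]
    outgroup: tuple[str, ...]
    out_dir: str
    coding_range: ColumnInterval | None = None
    frame: int = 0
    window_w: int = recombination.DEFAULT_WINDOW
    permutations: int = recombination.DEFAULT_PERMUTATIONS
    boot_replicates: int = 1000
    mc_replicates: int = cassette_scan.DEFAULT_MC_REPLICATES
    scan_window: int = cassette_scan.DEFAULT_SCAN_WINDOW
    min_count: int = cassette_scan.DEFAULT_MIN_COUNT
    gap_max: int = cassette_scan.DEFAULT_GAP_MAX
    selection_replicates: int = 500
    master_seed: int = 0

    def validate(self, aln: Alignment) -> None:
        for name, ids in (
            ("recipient", (self.recipient,)),
            ("background", self.background),
            ("candidates", self.candidates),
            ("outgroup", self.outgroup),
        ):
            for i in ids:
                if i not in aln.ids:
                    raise UnknownIdError(f"{name} id {i!r} not in alignment")
        for setting in (
            self.window_w, self.permutations, self.boot_replicates,
            self.mc_replicates, self.scan_window, self.min_count,
        ):
            if setting < 1:
                raise ValueError("all settings must be positive")


@dataclass(frozen=True)
class RunResult:
    out_dir: Path
    variants: list
    selection_result: selection.CodonSelectionResult | None
    phi_result: recombination.PhiResult
    cluster_report: cassette_scan.ClusterReport
    intervals: list[ColumnInterval]
    attribution: cassette_scan.DonorAttribution | None
    shift: cassette_scan.TopologyShiftReport | None
    manifest: dict = field(compare=False, default_factory=dict)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run every stage on one alignment and write the report bundle.

    Outputs in ``out_dir``: ``census.tsv``, ``selection.tsv``, ``phi.tsv``,
    ``cassettes.json``, ``tree_before.nwk``, ``tree_after.nwk``,
    ``intervals.tsv`` and ``manifest.json``.
    """
    aln = read_alignment(cfg.alignment_path)
    cfg.validate(aln)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "alignment": str(cfg.alignment_path),
        "recipient": cfg.recipient,
        "background": list(cfg.background),
        "candidates": list(cfg.candidates),
        "outgroup": list(cfg.outgroup),
        "coding_range": (
            [cfg.coding_range.start, cfg.coding_range.end]
            if cfg.coding_range
            else None
        ),
        "frame": cfg.frame,
        "settings": {
            "window_w": cfg.window_w,
            "permutations": cfg.permutations,
            "boot_replicates": cfg.boot_replicates,
            "mc_replicates": cfg.mc_replicates,
            "scan_window": cfg.scan_window,
            "min_count": cfg.min_count,
            "gap_max": cfg.gap_max,
            "selection_replicates": cfg.selection_replicates,
        },
        "master_seed": cfg.master_seed,
        "stage_seeds": {
            s: stage_seed(cfg.master_seed, s)
            for s in ("selection", "phi", "cluster", "topology")
        },
    }

    stage = "census"
    try:
        variants = selection.classify_variants(
            aln, cfg.recipient, list(cfg.background), cfg.coding_range, cfg.frame
        )
        with open(out / "census.tsv", "w") as fh:
            fh.write("# column (0-based)\tfocal\tbackground\teffect\n")
            fh.write(f"# variable columns in full alignment: {len(variable_columns(aln))}\n")
            for v in variants:
                fh.write(f"{v.column}\t{v.focal_state}\t{v.background_state}\t{v.effect}\n")

        stage = "selection"
        sel = None
        if cfg.coding_range is not None:
            sel = selection.selection_z_test(
                aln,
                cfg.coding_range,
                cfg.frame,
                replicates=cfg.selection_replicates,
                seed=stage_seed(cfg.master_seed, "selection"),
            )
            with open(out / "selection.tsv", "w") as fh:
                fh.write(selection.TSV_HEADER + "\n")
                fh.write(sel.tsv_row("coding") + "\n")

        stage = "phi"
        phi = recombination.phi_test(
            aln,
            window_w=cfg.window_w,
            permutations=cfg.permutations,
            seed=stage_seed(cfg.master_seed, "phi"),
            analytic=True,
        )
        with open(out / "phi.tsv", "w") as fh:
            fh.write(recombination.TSV_HEADER + "\n")
            fh.write(phi.tsv_row() + "\n")

        stage = "cluster"
        diffs = cassette_scan.difference_positions(
            aln, cfg.recipient, list(cfg.background)
        )
        report = cassette_scan.cluster_scan(
            diffs,
            aln.length,
            scan_window=cfg.scan_window,
            min_count=cfg.min_count,
            gap_max=cfg.gap_max,
            mc_replicates=cfg.mc_replicates,
            seed=stage_seed(cfg.master_seed, "cluster"),
        )
        intervals = cassette_scan.cassette_intervals(report)
        write_intervals(
            [(f"cassette{k + 1}", iv) for k, iv in enumerate(intervals)],
            out / "intervals.tsv",
        )

        stage = "attribution"
        attribution = None
        if intervals and cfg.candidates:
            attribution = cassette_scan.donor_attribution(
                aln, cfg.recipient, intervals, list(cfg.candidates)
            )

        stage = "topology"
        shift = None
        if intervals and cfg.outgroup:
            shift = cassette_scan.topology_shift(
                aln,
                cfg.recipient,
                intervals,
                list(cfg.outgroup),
                boot_replicates=cfg.boot_replicates,
                seed=stage_seed(cfg.master_seed, "topology"),
            )
            (out / "tree_before.nwk").write_text(shift.tree_before.newick() + "\n")
            (out / "tree_after.nwk").write_text(shift.tree_after.newick() + "\n")

        (out / "cassettes.json").write_text(
            cassette_scan.report_json(report, intervals, attribution, shift) + "\n"
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(
        out_dir=out,
        variants=variants,
        selection_result=sel,
        phi_result=phi,
        cluster_report=report,
        intervals=intervals,
        attribution=attribution,
        shift=shift,
        manifest=manifest,
    )
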