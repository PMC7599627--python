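"""End-to-end orchestration of the analysis stages.

Runs sex-linkage classification, strata demarcation, gene-content and
feminization statistics (k-mer copy number on demand) from one resolved
configuration, and writes a single JSON summary plus per-stage tables.
Every run writes the resolved configuration next to its outputs, and fixed
seeds make reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import pandas as pd

from . import __version__, feminization, genecontent, io, sexlink, strata

DEFAULTS = {
    "seed": 0,
    "window_size": 50_000,
    "min_covered": 30_000,
    "half_band": [0.35, 0.65],
    "z_threshold": 0.60,
    "similarity_window": 100_000,
    "min_aligned_fraction": 0.60,
    "min_aligned_bp": 65,
    "max_identity": 0.96,
    "max_segments": 4,
    "min_windows_per_segment": 5,
    "par_threshold": 0.985,
    "min_tpm": 1.0,
    "fold_change": 2.0,
    "ovary_threshold": 0.20,
    "ovary_denominator": "other",
    "exclude_nonconserved_s1": False,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def resolve_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULTS) - {"inputs", "outdir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    resolved = {**DEFAULTS, **config}
    resolved.setdefault("inputs", {})
    return resolved


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; return (and write) the summary dict."""
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(outdir / "resolved_config.json", {k: v for k, v in cfg.items()})
    inputs = cfg["inputs"]
    summary: dict = {
        "provenance": {
            "zwstrata_version": __version__,
            "seed": cfg["seed"],
            "parameter_hash": hashlib.sha256(
                json.dumps({k: cfg[k] for k in DEFAULTS}, sort_keys=True).encode()
            ).hexdigest()[:16],
        }
    }

    if "depth" in inputs:
        try:
            _log("sexlink", f"reading depth from {inputs['depth']}")
            tracks = io.read_depth_tsv(inputs["depth"])
            blocks_by_scaffold: dict = {}
            if "z_paf" in inputs:
                for b in io.read_alignments(inputs["z_paf"], "paf"):
                    blocks_by_scaffold.setdefault(b.w_scaffold, []).append(
                        (b.z_start, b.z_end)
                    )
            lengths = {
                sid: int(t.positions[-1]) if t.positions.size else 0
                for sid, t in tracks.items()
            }
            calls = sexlink.classify_genome(
                tracks,
                blocks_by_scaffold,
                lengths,
                window_size=cfg["window_size"],
                min_covered=cfg["min_covered"],
                half_band=tuple(cfg["half_band"]),
                z_threshold=cfg["z_threshold"],
            )
            io.write_scaffold_calls(outdir / "scaffold_calls.tsv", calls)
            io.write_bed(
                outdir / "w_candidates.bed",
                [
                    (c.scaffold_id, 0, lengths[c.scaffold_id], c.label)
                    for c in calls
                    if c.label == sexlink.LABEL_W
                ],
            )
            summary["sexlink"] = {
                "n_scaffolds": len(calls),
                "labels": pd.Series([c.label for c in calls]).value_counts().to_dict(),
            }
        except StageError:
            raise
        except Exception as e:
            raise StageError("sexlink", str(e)) from e

    if "alignments" in inputs:
        try:
            dialect = inputs.get("alignment_dialect", "paf")
            blocks = io.read_alignments(inputs["alignments"], dialect)
            kept = strata.filter_blocks(
                blocks,
                min_aligned_fraction=cfg["min_aligned_fraction"],
                min_aligned_bp=cfg["min_aligned_bp"],
                max_identity=cfg["max_identity"],
            )
            windows = strata.windowed_similarity(kept, window=cfg["similarity_window"])
            annos = strata.segment_strata(
                windows,
                max_segments=cfg["max_segments"],
                min_windows_per_segment=cfg["min_windows_per_segment"],
                par_threshold=cfg["par_threshold"],
            )
            io.write_similarity_windows(outdir / "similarity_windows.tsv", windows)
            io.write_strata_bed(outdir / "strata.bed", annos)
            summary["strata"] = {
                "n_blocks_in": len(blocks),
                "n_blocks_kept": len(kept),
                "strata": [
                    {
                        "label": a.label,
                        "z_start": a.z_start,
                        "z_end": a.z_end,
                        "mean_identity": a.mean_identity,
                        "n_windows": a.n_windows,
                    }
                    for a in annos
                ],
            }
        except Exception as e:
            raise StageError("strata", str(e)) from e

    if "gene_table" in inputs:
        try:
            df = pd.read_csv(inputs["gene_table"], sep="\t")
            records = genecontent.records_from_frame(df)
            report = genecontent.enrichment_report(
                records, exclude_nonconserved_s1=cfg["exclude_nonconserved_s1"]
            )
            try:
                r, p = genecontent.presence_hi_correlation(records)
                report["presence_hi_correlation"] = {"pearson_r": r, "p": p}
            except ValueError:
                pass
            io.write_json(outdir / "genecontent.json", report)
            summary["genecontent"] = report
        except Exception as e:
            raise StageError("genecontent", str(e)) from e

    if "expression" in inputs:
        try:
            tpm = io.read_expression_tsv(inputs["expression"])
            tpm = feminization.mean_over_replicates(tpm)
            calls = feminization.call_female_bias(
                tpm, min_tpm=cfg["min_tpm"], fold=cfg["fold_change"]
            )
            dominance = {
                gid: feminization.ovary_dominance(
                    row,
                    threshold=cfg["ovary_threshold"],
                    denominator=cfg["ovary_denominator"],
                )
                for gid, row in tpm.iterrows()
            }
            bias_df = pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "tissue": c.tissue,
                        "f_over_m": c.f_over_m,
                        "female_biased": c.female_biased,
                    }
                    for c in calls
                ]
            )
            bias_df.to_csv(outdir / "bias_calls.tsv", sep="\t", index=False, float_format="%.6g")
            summary["feminization"] = {
                "n_bias_calls": len(calls),
                "n_female_biased": int(sum(c.female_biased for c in calls)),
                "n_ovary_dominant": int(sum(dom for _, dom in dominance.values())),
            }
        except Exception as e:
            raise StageError("feminization", str(e)) from e

    io.write_json(outdir / "summary.json", summary)
    return summary
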