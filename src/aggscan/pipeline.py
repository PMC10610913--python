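"""End-to-end orchestration: enumerate -> count -> score -> classify -> embed.

``run_all`` chains the screen stages over three sequencing pools and writes
machine-readable tables for each figure-style output (enrichment matrix,
per-variant records, residue classification, optional embedding), plus a run
manifest recording the configuration, input hashes, and seeds so that a rerun
reproduces every deterministic stage byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .asyn import asyn_reference
from .counts import POOL_LABELS, CountTable, count_fastq
from .enrichment import (
    EnrichmentMatrix,
    build_matrix,
    records_to_frame,
    score_records,
    stop_codon_fdr,
    stop_read_enrichment,
)
from .library import CodingSequence, enumerate_nns
from .residues import classify_matrix, embed_profiles


@dataclass
class PipelineConfig:
    fasta: str | None = None            # WT CDS; bundled aSyn reference if None
    mutable_range: tuple[int, int] | None = None
    min_input_count: int = 10
    pseudocount: float = 0.0
    otsu_bins: int = 256
    run_embedding: bool = False
    perplexity: float = 30.0
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    pools: dict[str, str | Path],
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run the full screen analysis over the three sequencing pools.

    ``pools`` maps pool labels (input_library, fret_pos, fret_neg; fret_neg
    optional) to merged-read FASTQ paths.  Returns the run manifest (also
    written to ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label in ("input_library", "fret_pos"):
        if label not in pools:
            raise ValueError(f"missing required pool {label!r}")
    unknown = set(pools) - set(POOL_LABELS)
    if unknown:
        raise ValueError(f"unknown pool labels {sorted(unknown)}")

    wt = (
        CodingSequence.from_fasta(config.fasta)
        if config.fasta
        else asyn_reference()
    )
    db = enumerate_nns(wt, config.mutable_range)

    stage = "count"
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "wt_name": wt.name,
        "n_protein_variants": db.n_protein_variants,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in pools.items()},
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "stages": {},
        "outputs": {},
    }
    try:
        tables: dict[str, CountTable] = {}
        for label, path in pools.items():
            ct = count_fastq(path, db, label)
            tables[label] = ct
            p = out / f"{label}.counts.tsv"
            ct.write_tsv(p, db)
            manifest["outputs"][f"counts_{label}"] = str(p)
        manifest["stages"]["count"] = {
            label: {"total": t.total, "matched": t.matched, "wt": t.wt_count}
            for label, t in tables.items()
        }

        stage = "score"
        records = score_records(
            tables["fret_pos"], tables["input_library"], db,
            min_input_count=config.min_input_count, pseudocount=config.pseudocount,
        )
        rec_path = out / "records.tsv"
        records_to_frame(records, db).to_csv(rec_path, sep="\t", index=False)
        matrix = build_matrix(records, db)
        mat_path = out / "matrix.tsv"
        matrix.write_tsv(mat_path)
        manifest["outputs"]["records"] = str(rec_path)
        manifest["outputs"]["matrix"] = str(mat_path)
        manifest["stages"]["score"] = {
            "n_scored": sum(1 for r in records if r.re is not None),
            "n_missing_cells": matrix.n_missing(),
            "stop_fdr_re_positive": stop_codon_fdr(records),
            "stop_read_enrichment": stop_read_enrichment(records),
        }

        stage = "classify"
        cls = classify_matrix(matrix, bins=config.otsu_bins)
        cls_path = out / "classification.tsv"
        import pandas as pd

        pd.DataFrame(
            {
                "position": p,
                "median_re": cls.medians[p],
                "class": "inhibitory" if p in cls.inhibitory else "tolerant",
            }
            for p in sorted(cls.medians)
        ).to_csv(cls_path, sep="\t", index=False)
        (out / "intervals.txt").write_text(cls.render_intervals() + "\n")
        manifest["outputs"]["classification"] = str(cls_path)
        manifest["outputs"]["intervals"] = str(out / "intervals.txt")
        manifest["stages"]["classify"] = {
            "otsu_threshold": cls.threshold,
            "n_inhibitory": len(cls.inhibitory),
            "intervals": cls.render_intervals(),
        }

        if config.run_embedding:
            stage = "embed"
            emb = embed_profiles(matrix, perplexity=config.perplexity, seed=config.seed)
            emb_path = out / "embedding.tsv"
            pd.DataFrame(
                {
                    "position": p,
                    "x": emb.coords[i, 0],
                    "y": emb.coords[i, 1],
                    "class": "inhibitory" if p in cls.inhibitory else "tolerant",
                }
                for i, p in enumerate(emb.positions)
            ).to_csv(emb_path, sep="\t", index=False)
            manifest["outputs"]["embedding"] = str(emb_path)
            manifest["stages"]["embed"] = {"perplexity": emb.perplexity, "seed": emb.seed}
    except Exception as err:
        manifest["status"] = "partial"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["status"] = "complete"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def export_heatmap_table(matrix: EnrichmentMatrix, path: str | Path) -> None:
    """Figure-layout TSV: 20 substitution rows in display order, positions as
    columns, cells holding an RE value, 'NA' (masked) or 'WT' (reference)."""
    matrix.write_tsv(path)
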