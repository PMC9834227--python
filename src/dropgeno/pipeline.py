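"""End-to-end pipeline: simulate -> genotype -> annotate -> mispriming ->
qc -> evaluate -> lineage, with a JSON manifest of every stage's inputs,
outputs, parameters and checksums.

Stages write under <outdir>/<stage>/ and never touch another stage's
outputs; rerunning with the same seed reproduces the checksums of every
deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import pysam

from . import evaluate as ev
from . import expression as xp
from . import io as dgio
from .annotation import canonical_by_gene, filter_intronic, kit_distance, load_annotation
from .config import RunConfig, sim_config_from_block
from .genotype import CountingParams, annotate_calls, count_alleles
from .lineage import DEFAULT_GERM_LAYER_MAP, classify_origin, load_germ_layer_map
from .mispriming import nearest_capture_site, scan_polyA
from .simulate import DEFAULT_READ_LENGTH, simulate_dataset

log = logging.getLogger(__name__)

_KIT_LONG = {"3p": "three_prime", "5p": "five_prime"}


def file_checksum(path: str | Path) -> str:
    """sha256 of a file; BAMs are hashed over their SAM text so the digest
    reflects alignment content, not container bytes."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".bam":
        with pysam.AlignmentFile(str(path), "rb") as bam:
            h.update(str(bam.header).encode())
            for read in bam.fetch(until_eof=True):
                h.update(read.to_string().encode())
                h.update(b"\n")
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_entry(stage: str, params: dict, inputs: list, outputs: list, seed: int, t0: float) -> dict:
    return {
        "stage": stage,
        "parameters": params,
        "inputs": [str(p) for p in inputs],
        "outputs": [
            {"path": str(p), "sha256": file_checksum(p)} for p in outputs if Path(p).is_file()
        ],
        "seed": seed,
        "elapsed_s": round(time.monotonic() - t0, 3),
    }


def run_all(config: RunConfig) -> dict:
    """Run the configured stages in pipeline order and return the manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "kit": config.kit, "stages": []}
    inputs = dict(config.inputs)
    kit_end = _KIT_LONG[config.kit]
    read_length = config.simulate["read_length"] or DEFAULT_READ_LENGTH[kit_end]

    order = [s for s in ("simulate", "genotype", "annotate", "mispriming", "qc", "evaluate", "lineage") if s in config.stages]
    state: dict = {}
    for stage in order:
        t0 = time.monotonic()
        log.info("stage %s: starting", stage)
        try:
            if stage == "simulate":
                sim_cfg = sim_config_from_block(config.simulate, config.seed)
                paths = simulate_dataset(sim_cfg, outdir / "simulate")
                inputs.update(
                    bam=str(paths["bam"]), vcf=str(paths["vcf"]), gtf=str(paths["gtf"]),
                    fasta=str(paths["fasta"]), counts=str(paths["counts"]),
                    cell_metadata=str(paths["cell_metadata"]),
                )
                outs = [paths["bam"], paths["fasta"], paths["gtf"], paths["vcf"],
                        paths["counts"] / "matrix.mtx", paths["cell_metadata"],
                        outdir / "simulate" / "truth_cells.tsv"]
                params = dict(config.simulate)
            elif stage == "genotype":
                variants = dgio.read_vcf(inputs["vcf"])
                meta = pd.read_csv(inputs["cell_metadata"], sep="\t")
                params_obj = CountingParams(
                    min_mapping_quality=int(config.genotype["min_mapping_quality"]),
                    min_base_quality=int(config.genotype["min_base_quality"]),
                    umi_consensus=config.genotype["umi_consensus"],
                    call_policy=config.genotype["call_policy"],
                    valid_barcodes=frozenset(meta["barcode"].astype(str)),
                )
                matrices = count_alleles(inputs["bam"], variants, params_obj)
                gdir = outdir / "genotype"
                dgio.write_genotype_matrices(matrices, gdir)
                state["matrices"] = matrices
                state["metadata"] = meta.set_index("barcode")
                outs = [gdir / f for f in ("ref.mtx", "alt.mtx", "barcodes.tsv", "variants.tsv", "calls.tsv")]
                params = dict(config.genotype)
            elif stage == "annotate":
                annotation = load_annotation(
                    inputs["gtf"],
                    mane_ids=(
                        pd.read_csv(inputs["mane_ids"], sep="\t", header=None)[0].tolist()
                        if inputs.get("mane_ids")
                        else None
                    ),
                )
                variants = dgio.read_vcf(inputs["vcf"])
                kept, dropped = filter_intronic(variants, annotation)
                dist_df = pd.DataFrame(
                    [
                        {
                            "variant": vd.variant.id, "gene_id": vd.variant.gene_id,
                            "transcript_id": vd.transcript_id, "tx_coord": vd.tx_coord,
                            "dist_5p": vd.dist_5p, "dist_3p": vd.dist_3p,
                            "dist_relevant": kit_distance(vd, kit_end),
                        }
                        for vd in kept
                    ]
                )
                adir = outdir / "annotate"
                adir.mkdir(exist_ok=True)
                dist_df.to_csv(adir / "distances.tsv", sep="\t", index=False)
                pd.DataFrame(
                    [{"variant": v.id, "reason": r} for v, r in dropped]
                ).to_csv(adir / "dropped.tsv", sep="\t", index=False)
                state["annotation"] = annotation
                state["variant_distances"] = kept
                state["distances"] = dist_df
                outs = [adir / "distances.tsv", adir / "dropped.tsv"]
                params = {"kit": config.kit}
            elif stage == "mispriming":
                genome = dgio.read_fasta(inputs["fasta"])
                annotation = state.get("annotation") or load_annotation(inputs["gtf"])
                canon = canonical_by_gene(annotation)
                mp = config.mispriming
                site_rows, eff_rows = [], []
                sites_by_tx = {}
                for gid, tx in canon.items():
                    sites = scan_polyA(
                        tx.spliced_sequence(genome), int(mp["min_run"]),
                        int(mp["window"]), float(mp["min_frac"]), tx.transcript_id,
                    )
                    sites_by_tx[tx.transcript_id] = sites
                    site_rows += [
                        {
                            "transcript_id": s.transcript_id, "tx_coord": s.tx_coord,
                            "end": s.end, "run_length": s.run_length,
                            "window_A_fraction": round(s.window_A_fraction, 4),
                        }
                        for s in sites
                    ]
                for vd in state.get("variant_distances", []):
                    site, eff = nearest_capture_site(
                        vd, sites_by_tx.get(vd.transcript_id, []), kit_end, read_length
                    )
                    eff_rows.append(
                        {
                            "variant": vd.variant.id,
                            "dist_relevant": kit_distance(vd, kit_end),
                            "effective_distance": eff,
                            "via_internal_site": site.tx_coord if site else None,
                        }
                    )
                mdir = outdir / "mispriming"
                mdir.mkdir(exist_ok=True)
                pd.DataFrame(site_rows).to_csv(mdir / "sites.tsv", sep="\t", index=False)
                eff_df = pd.DataFrame(eff_rows)
                eff_df.to_csv(mdir / "effective_distances.tsv", sep="\t", index=False)
                state["effective"] = eff_df
                outs = [mdir / "sites.tsv", mdir / "effective_distances.tsv"]
                params = dict(mp)
            elif stage == "qc":
                counts = dgio.read_counts_mtx(inputs["counts"])
                qc = xp.qc_metrics(counts)
                keep = xp.filter_cells(qc, float(config.qc["max_pct_mito"]))
                mean_expr = xp.mean_lognorm(counts[keep]) if keep else pd.Series(dtype=float)
                qdir = outdir / "qc"
                qdir.mkdir(exist_ok=True)
                qc.to_csv(qdir / "cell_qc.tsv", sep="\t")
                mean_expr.rename("mean_lognorm_expr").to_csv(qdir / "mean_expression.tsv", sep="\t")
                state["mean_expr"] = mean_expr
                outs = [qdir / "cell_qc.tsv", qdir / "mean_expression.tsv"]
                params = dict(config.qc)
            elif stage == "evaluate":
                matrices = state["matrices"]
                dist_map = {}
                if "distances" in state:
                    eff = state.get("effective")
                    eff_map = (
                        dict(zip(eff["variant"], eff["effective_distance"]))
                        if eff is not None
                        else {}
                    )
                    for _, row in state["distances"].iterrows():
                        dist_map[row["variant"]] = {
                            "dist_relevant": row["dist_relevant"],
                            "effective_distance": eff_map.get(row["variant"], row["dist_relevant"]),
                        }
                records = ev.build_detection_records(
                    matrices, dist_map, state.get("mean_expr"), kit=config.kit
                )
                e = config.evaluate
                by_dist = ev.stratify_by_distance(
                    records, int(e["near_threshold"]), int(e["far_threshold"]),
                    float(e["detect_threshold"]),
                )
                by_expr = ev.stratify_by_expression(
                    records, tuple(e["expr_thresholds"]), float(e["detect_threshold"])
                )
                annotated = annotate_calls(matrices, state["metadata"])
                vaf_frames = []
                for v in matrices.variants:
                    t = ev.per_cluster_vaf(annotated, variant=v.id)
                    t.insert(0, "variant", v.id)
                    vaf_frames.append(t)
                vaf = pd.concat(vaf_frames, ignore_index=True)
                edir = outdir / "evaluate"
                edir.mkdir(exist_ok=True)
                records.to_csv(edir / "detection_records.tsv", sep="\t", index=False)
                by_dist.to_csv(edir / "detection_by_distance.tsv", sep="\t", index=False)
                by_expr.to_csv(edir / "detection_by_expression.tsv", sep="\t", index=False)
                vaf.to_csv(edir / "per_cluster_vaf.tsv", sep="\t", index=False)
                null_present = any(v.role == "null_set" for v in matrices.variants)
                if null_present:
                    fpr = ev.false_positive_rate(matrices)
                    (edir / "false_positive_rate.json").write_text(
                        json.dumps(fpr.__dict__, default=list, indent=1)
                    )
                state["vaf"] = vaf
                state["annotated"] = annotated
                outs = sorted(edir.glob("*"))
                params = dict(e)
            elif stage == "lineage":
                germ_map = (
                    load_germ_layer_map(config.lineage["germ_map"])
                    if config.lineage["germ_map"]
                    else DEFAULT_GERM_LAYER_MAP
                )
                rows = []
                for v in state["matrices"].variants:
                    if v.role != "somatic_candidate":
                        continue
                    call = classify_origin(
                        state["vaf"][state["vaf"]["variant"] == v.id],
                        germ_map,
                        int(config.lineage["min_alt_cells_per_layer"]),
                        variant=v.id,
                    )
                    rows.append(
                        {
                            "variant": call.variant,
                            "classification": call.classification,
                            "layers_with_alt": ",".join(sorted(call.layers_with_alt)),
                            "n_alt_per_layer": json.dumps(call.n_alt_per_layer, sort_keys=True),
                            "excluded_clusters": ",".join(call.excluded_clusters),
                        }
                    )
                ldir = outdir / "lineage"
                ldir.mkdir(exist_ok=True)
                pd.DataFrame(rows).to_csv(ldir / "lineage_calls.tsv", sep="\t", index=False)
                outs = [ldir / "lineage_calls.tsv"]
                params = dict(config.lineage)
            else:  # pragma: no cover
                raise AssertionError(stage)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline halted at stage '{stage}': {exc}") from exc

        manifest["stages"].append(
            _manifest_entry(stage, params, sorted(set(filter(None, inputs.values()))), outs, config.seed, t0)
        )
        log.info("stage %s: done (%.2fs)", stage, time.monotonic() - t0)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
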