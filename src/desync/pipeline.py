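"""Configured, seedable end-to-end pipeline with manifest-based re-runs.

Stage order: simulate → fc → ngsc → infer → resample → embed → report.
Each stage reads/writes plain TSV under the output directory; a JSON
manifest records the config snapshot and SHA-256 hashes of every output so
re-runs with an unchanged config can skip completed stages, and exact
stages are bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import embedding as emb
from . import entropy, inference, resampling
from .cohort import CohortConfig, generate_cohort
from . import io as dio

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("desync")

STAGES = ("simulate", "fc", "ngsc", "infer", "resample", "embed", "report")


@dataclass
class RunConfig:
    outdir: str = "desync_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: dict = field(default_factory=dict)
    bootstrap_B: int = 199
    n_perm: int = 500
    tfce_E: float = resampling.TFCE_E
    tfce_H: float = resampling.TFCE_H
    mds_k: int = 4
    contrast_condition: str = "psilocybin"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path):
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_fcs(out: Path):
    meta = dio.read_metadata_table(out / "metadata.tsv")
    from .cohort import ScanRecord

    fcs = []
    for _, row in meta.iterrows():
        signals, _ = dio.read_scan_matrix(out / row["scan_path"])
        scan = ScanRecord(
            participant_id=row["participant"],
            session_id=row["session"],
            day_index=int(row["day"]),
            condition=row["condition"],
            task=bool(row["task"]),
            mean_fd=float(row["mean_fd"]),
            signals=signals,
        )
        fcs.append(conn.compute_fc(scan))
    return meta, fcs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    prev = {}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
    cfg_hash = config.config_hash()
    manifest = {"config_hash": cfg_hash, "stages": {}}
    config.to_yaml(out / "config.yaml")

    def done(stage: str, outputs: list[Path]):
        manifest["stages"][stage] = {
            "outputs": {p.name: _hash_file(p) for p in outputs}
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def can_skip(stage: str, outputs: list[Path]) -> bool:
        if prev.get("config_hash") != cfg_hash:
            return False
        rec = prev.get("stages", {}).get(stage)
        if not rec:
            return False
        for p in outputs:
            if not p.exists() or _hash_file(p) != rec["outputs"].get(p.name):
                log.warning("stage %s: stale output %s, re-running", stage, p.name)
                return False
        manifest["stages"][stage] = rec
        return True

    run = set(config.stages)

    if "simulate" in run:
        outputs = [out / "metadata.tsv", out / "parcels.tsv",
                   out / "parcel_edges.tsv"]
        if not can_skip("simulate", outputs):
            log.info("simulate: generating cohort")
            cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
            scans, reports, parcels, _ = generate_cohort(cohort_cfg)
            (out / "scans").mkdir(exist_ok=True)
            rows = []
            for scan in scans:
                rel = f"scans/{scan.scan_id}.tsv"
                dio.write_scan_matrix(out / rel, scan.signals,
                                      parcels.parcel_ids)
                rows.append(
                    {
                        "scan_id": scan.scan_id,
                        "participant": scan.participant_id,
                        "session": scan.session_id,
                        "day": scan.day_index,
                        "condition": scan.condition,
                        "task": scan.task,
                        "mean_fd": scan.mean_fd,
                        "scan_path": rel,
                    }
                )
            dio.write_metadata_table(out / "metadata.tsv", pd.DataFrame(rows))
            dio.write_parcel_table(out, parcels)
            pd.DataFrame(
                [
                    {
                        "participant": r.participant_id,
                        "session": r.session_id,
                        "meq30_total": r.meq30_total,
                        **r.subscales,
                    }
                    for r in reports
                ]
            ).to_csv(out / "meq30.tsv", sep="\t", index=False)
            done("simulate", outputs)

    fcs = None
    if "fc" in run:
        outputs = [out / "scan_distance.tsv", out / "condition_fc_change.tsv"]
        log.info("fc: connectivity and distance matrices")
        meta, fcs = _load_fcs(out)
        sdm = conn.scan_distance_matrix(fcs)
        dio.write_labeled_matrix(
            out / "scan_distance.tsv", sdm.values, meta["scan_id"]
        )
        means = conn.condition_fc_change(sdm)
        normed = conn.normalize_fc_change(means)
        pd.DataFrame(
            {
                "condition": list(means),
                "mean_distance": [means[c] for c in means],
                "normalized": [normed[c] for c in means],
            }
        ).to_csv(out / "condition_fc_change.tsv", sep="\t", index=False)
        done("fc", outputs)

    if "ngsc" in run:
        log.info("ngsc: spatial entropy per scan")
        meta = dio.read_metadata_table(out / "metadata.tsv")
        vals = []
        for _, row in meta.iterrows():
            signals, _ = dio.read_scan_matrix(out / row["scan_path"])
            vals.append(entropy.ngsc(signals).whole_brain)
        meta["ngsc"] = vals
        meta.to_csv(out / "metadata_ngsc.tsv", sep="\t", index=False)
        done("ngsc", [out / "metadata_ngsc.tsv"])

    if "infer" in run or "resample" in run or "embed" in run or "report" in run:
        meta = dio.read_metadata_table(out / "metadata.tsv")
        if fcs is None:
            meta, fcs = _load_fcs(out)

    if "infer" in run:
        log.info("infer: scan-level mixed models")
        scans = [f.scan for f in fcs]
        y = _whole_brain_change_scores(meta, fcs)
        obs = inference.observations_from_scans(scans, y)
        fit = inference.fit_lme(
            obs, contrast_condition=config.contrast_condition
        )
        fit.summary().to_csv(out / "lme_fc_change.tsv", sep="\t", index=False)
        done("infer", [out / "lme_fc_change.tsv"])

    if "resample" in run:
        log.info("resample: wild bootstrap + TFCE + spin")
        parcels = dio.read_parcel_table(out)
        maps, design = _fc_change_maps(meta, fcs)
        sm = resampling.wild_bootstrap_map(
            maps,
            design,
            B=config.bootstrap_B,
            seed=config.seed,
            contrast_condition=config.contrast_condition,
        )
        sm.tfce_pos = resampling.tfce(
            sm.t, parcels.adjacency, config.tfce_E, config.tfce_H
        )
        null_tfce = np.array(
            [
                resampling.tfce(row, parcels.adjacency, config.tfce_E,
                                config.tfce_H)
                for row in sm.null_t
            ]
        )
        sm.p = resampling.tfce_p_values(sm.tfce_pos, null_tfce)
        pd.DataFrame(
            {
                "parcel_id": parcels.parcel_ids,
                "t": sm.t,
                "tfce": sm.tfce_pos,
                "p": sm.p,
            }
        ).to_csv(out / "statmap.tsv", sep="\t", index=False)
        mean_map = maps[
            (design["condition"] == config.contrast_condition).to_numpy()
        ].mean(axis=0)
        spin = resampling.spin_test(
            mean_map, parcels, n_perm=config.n_perm, seed=config.seed
        )
        pd.DataFrame(
            {
                "network": spin.networks,
                "observed": [spin.observed[n] for n in spin.networks],
                "p": [spin.p[n] for n in spin.networks],
            }
        ).to_csv(out / "spin_test.tsv", sep="\t", index=False)
        done("resample", [out / "statmap.tsv", out / "spin_test.tsv"])

    if "embed" in run:
        log.info("embed: classical MDS")
        sdm = conn.scan_distance_matrix(fcs)
        k = min(config.mds_k, len(fcs) - 1)
        embd = emb.classical_mds(sdm.values, k=k, labels=sdm.labels)
        vectors = emb.fc_vectors(fcs)
        emb.dimension_eigenweights(embd, vectors)
        emb.orient_to_condition(
            embd, sdm.labels["condition"].to_numpy(), config.contrast_condition
        )
        df = pd.DataFrame(
            embd.coordinates, columns=[f"dim{i+1}" for i in range(embd.k)]
        )
        df.insert(0, "scan_id", meta["scan_id"])
        df["condition"] = meta["condition"].to_numpy()
        df.to_csv(out / "mds_embedding.tsv", sep="\t", index=False)
        done("embed", [out / "mds_embedding.tsv"])

    if "report" in run:
        summary = pd.read_csv(out / "condition_fc_change.tsv", sep="\t")
        report_path = out / "report.txt"
        with open(report_path, "w", encoding="utf-8") as fh:
            fh.write("Normalized whole-brain FC change by condition\n")
            fh.write(summary.to_string(index=False))
            fh.write("\n")
        done("report", [report_path])

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _baseline_rest_fcs(meta: pd.DataFrame, fcs) -> dict[str, list]:
    by_part: dict[str, list] = {}
    for (_, row), fc in zip(meta.iterrows(), fcs):
        if row["condition"] == "baseline" and not row["task"]:
            by_part.setdefault(row["participant"], []).append(fc)
    return by_part


def _whole_brain_change_scores(meta: pd.DataFrame, fcs) -> np.ndarray:
    """Whole-brain FC change per scan vs same-participant baseline rest
    scans (same-session baselines excluded)."""
    base = _baseline_rest_fcs(meta, fcs)
    scores = np.full(len(fcs), np.nan)
    for i, ((_, row), fc) in enumerate(zip(meta.iterrows(), fcs)):
        refs = [
            b
            for b in base.get(row["participant"], [])
            if b is not fc and b.scan.session_id != row["session"]
        ]
        if refs:
            scores[i] = float(
                np.mean([conn.whole_brain_fc_change(fc, b) for b in refs])
            )
    return scores


def _fc_change_maps(meta: pd.DataFrame, fcs):
    """Per-scan per-parcel FC change maps and the matching design table."""
    base = _baseline_rest_fcs(meta, fcs)
    rows, maps = [], []
    for (_, row), fc in zip(meta.iterrows(), fcs):
        refs = [
            b
            for b in base.get(row["participant"], [])
            if b is not fc and b.scan.session_id != row["session"]
        ]
        if not refs:
            continue
        maps.append(conn.fc_change_map(fc, refs).values)
        rows.append(row)
    design = pd.DataFrame(rows).reset_index(drop=True)
    design = design.rename(columns={"mean_fd": "fd"})
    return np.array(maps), design
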